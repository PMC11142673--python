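"""Corridor priority index: screened, standardized features -> PCA ->
distance from the origin in the first-3-component space -> three classes.

The index rests on the premise that shorter, well-protected, well-forested
corridors linking large lowland reserves to large, intact, elevationally
diverse highland patches are the best climate-adaptation candidates.
Corridor length is inverted so shorter corridors load in the favorable
direction; all variables are standardized (mean 0, sd 1, n-1 divisor)
before the PCA; the index of corridor i is sqrt(s_i1^2 + s_i2^2 + s_i3^2)
over its first three component scores. Classes: low < 2, medium 2-4
(inclusive both ends), high > 4.

Note one known property of the construction: distance from the origin is
direction-blind, so a corridor extreme on the *unfavorable* side of a
component also scores high. The index is implemented exactly as defined;
see the methods note for discussion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DegenerateVariableError, JoinError

__all__ = [
    "FeatureVariable",
    "FeatureSpec",
    "PriorityModel",
    "assemble_features",
    "screen_collinear",
    "standardize",
    "fit_pca",
    "priority_scores",
    "classify_priority",
    "prioritize",
]

log = logging.getLogger(__name__)

LOW_UPPER = 2.0
HIGH_LOWER = 4.0
N_COMPONENTS = 3


@dataclass(frozen=True)
class FeatureVariable:
    name: str                    # column in the source table
    source: str                  # "corridor" | "start" | "end"
    invert: bool = False
    include: bool = True

    @property
    def label(self) -> str:
        return f"{self.source}_{self.name}"


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered variable list feeding the PCA, with screening preferences.

    The default list combines corridor variables (inverted length,
    elevation range, protection, overlapping protected areas and KBAs, mean
    biomass), start-node variables (area, elevation range) and end-patch
    variables (area, elevation range, protection). ``drop_preference``
    names the variables designated to be dropped when the collinearity
    screen flags a pair containing them — by default the corridor PA count
    (kept variable: length) and the end-patch area (kept variable: end
    elevation range).
    """

    variables: tuple[FeatureVariable, ...] = (
        FeatureVariable("length_km", "corridor", invert=True),
        FeatureVariable("elev_range_m", "corridor"),
        FeatureVariable("protection_pct", "corridor"),
        FeatureVariable("n_pas", "corridor"),
        FeatureVariable("n_kbas", "corridor"),
        FeatureVariable("mean_biomass", "corridor"),
        FeatureVariable("area_km2", "start"),
        FeatureVariable("elev_range_m", "start"),
        FeatureVariable("area_km2", "end"),
        FeatureVariable("elev_range_m", "end"),
        FeatureVariable("protection_pct", "end"),
    )
    drop_preference: tuple[str, ...] = ("corridor_n_pas", "end_area_km2")
    rho_threshold: float = 0.7

    def __post_init__(self) -> None:
        included = [v for v in self.variables if v.include]
        if len(included) < 2:
            raise ConfigError("feature spec must include at least 2 variables")

    @property
    def included(self) -> tuple[FeatureVariable, ...]:
        return tuple(v for v in self.variables if v.include)


def assemble_features(
    corridor_table: pd.DataFrame,
    start_table: pd.DataFrame,
    end_table: pd.DataFrame,
    spec: FeatureSpec = FeatureSpec(),
) -> pd.DataFrame:
    """One feature row per corridor, joined to its start node and end patch.

    ``corridor_table`` must carry ``start_id`` (-> start table
    ``reserve_id``) and ``patch_id`` (-> end table). Invert-flagged
    variables are negated. A corridor that fails either join is an error —
    no imputation. Columns follow spec order, labelled source_name; the
    index is corridor_id.
    """
    start_idx = start_table.set_index("reserve_id")
    end_idx = end_table.set_index("patch_id")

    unmatched_start = sorted(set(corridor_table["start_id"]) - set(start_idx.index))
    unmatched_end = sorted(set(corridor_table["patch_id"]) - set(end_idx.index))
    if unmatched_start or unmatched_end:
        raise JoinError(
            f"corridors with no matching start node: {unmatched_start}; "
            f"no matching end patch: {unmatched_end}"
        )

    out = pd.DataFrame(index=corridor_table["corridor_id"].to_numpy())
    out.index.name = "corridor_id"
    for var in spec.included:
        if var.source == "corridor":
            col = corridor_table[var.name].to_numpy(dtype=float)
        elif var.source == "start":
            col = start_idx.loc[corridor_table["start_id"], var.name].to_numpy(dtype=float)
        elif var.source == "end":
            col = end_idx.loc[corridor_table["patch_id"], var.name].to_numpy(dtype=float)
        else:
            raise ConfigError(f"unknown variable source {var.source!r}")
        out[var.label] = -col if var.invert else col
    return out


def screen_collinear(
    matrix: pd.DataFrame,
    rho_threshold: float = 0.7,
    drop_preference: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop one variable from each highly rank-correlated pair.

    For every pair with \\|Spearman rho\\| >= ``rho_threshold``, the variable
    named in ``drop_preference`` is removed; if neither is designated, the
    later column in spec order goes. Returns (reduced matrix, report); the
    report lists each flagged pair, its rho, and the decision.
    """
    if len(matrix) < 3:
        raise ConfigError("collinearity screen needs at least 3 rows")
    cols = list(matrix.columns)
    dropped: set[str] = set()
    report_rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a in dropped or b in dropped:
                continue
            with warnings.catch_warnings():
                # constant columns yield NaN rho; handled below
                warnings.simplefilter("ignore", sps.ConstantInputWarning)
                rho = sps.spearmanr(matrix[a], matrix[b]).statistic
            if np.isnan(rho) or abs(rho) < rho_threshold:
                continue
            if a in drop_preference:
                drop = a
            elif b in drop_preference:
                drop = b
            else:
                drop = b  # later column in spec order
            dropped.add(drop)
            report_rows.append({"var_a": a, "var_b": b, "rho": float(rho), "dropped": drop})
    report = pd.DataFrame(report_rows, columns=["var_a", "var_b", "rho", "dropped"])
    return matrix.drop(columns=sorted(dropped)), report


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise z-scores (mean 0, sd 1; n-1 divisor). Returns (z, means, sds)."""
    means = matrix.mean()
    sds = matrix.std(ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    if constant:
        raise DegenerateVariableError(
            f"variable(s) {constant} are constant and cannot be standardized"
        )
    return (matrix - means) / sds, means, sds


@dataclass
class PriorityModel:
    """Fitted PCA prioritization model.

    Carries everything needed to score new corridors: the feature spec,
    the standardization parameters, the loading matrix (columns are unit
    eigenvectors of the correlation matrix, eigenvalues non-increasing),
    the retained component count and the class thresholds.
    """

    feature_names: list[str]
    means: pd.Series
    sds: pd.Series
    loadings: np.ndarray        # (n_vars, n_kept_components)
    eigenvalues: np.ndarray     # all eigenvalues, descending
    n_components: int = N_COMPONENTS
    variance_explained: float = float("nan")
    low_upper: float = LOW_UPPER
    high_lower: float = HIGH_LOWER


def fit_pca(z: pd.DataFrame, n_components: int = N_COMPONENTS) -> PriorityModel:
    """PCA of the standardized feature matrix.

    Eigendecomposition of the correlation matrix (the covariance of the
    z-matrix, n-1 divisor), components ordered by eigenvalue. Loading signs
    follow a fixed convention (the entry of largest magnitude in each
    column is positive) so outputs are reproducible; the index is invariant
    to this choice. Components beyond the matrix rank are dropped with a
    warning, and the retained count never exceeds the variable count.
    """
    n, p = z.shape
    if n <= p:
        log.warning("PCA with n=%d rows <= p=%d variables; interpret with care", n, p)
    corr = np.cov(z.to_numpy(dtype=float), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign convention
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1
    rank = int((eigvals > 1e-10 * max(eigvals.max(), 1.0)).sum())
    kept = min(n_components, p)
    if kept > rank:
        log.warning("requested %d components but rank is %d; keeping %d", kept, rank, rank)
        kept = rank
    total = eigvals.sum()
    return PriorityModel(
        feature_names=list(z.columns),
        means=pd.Series(dtype=float),
        sds=pd.Series(dtype=float),
        loadings=eigvecs[:, :kept],
        eigenvalues=eigvals,
        n_components=kept,
        variance_explained=float(eigvals[:kept].sum() / total) if total > 0 else float("nan"),
    )


def classify_priority(index: float, low_upper: float = LOW_UPPER,
                      high_lower: float = HIGH_LOWER) -> str:
    """low on [0, low_upper); medium on [low_upper, high_lower]; high above."""
    if index < 0 or not np.isfinite(index):
        raise ValueError(f"priority index must be finite and >= 0, got {index}")
    if index < low_upper:
        return "low"
    if index <= high_lower:
        return "medium"
    return "high"


def priority_scores(model: PriorityModel, z: pd.DataFrame) -> pd.DataFrame:
    """Component scores, index, and class for every corridor.

    index_i = Euclidean norm of corridor i's scores on the retained
    components (distance from the origin of the component space).
    """
    if model.n_components > model.loadings.shape[1]:
        raise ConfigError(
            f"model retains {model.loadings.shape[1]} components, "
            f"{model.n_components} requested"
        )
    scores = z.to_numpy(dtype=float) @ model.loadings
    index = np.linalg.norm(scores, axis=1)
    out = pd.DataFrame(
        {f"pc{j + 1}": scores[:, j] for j in range(scores.shape[1])},
        index=z.index,
    )
    out["index"] = index
    out["priority_class"] = [
        classify_priority(v, model.low_upper, model.high_lower) for v in index
    ]
    return out


def prioritize(
    corridor_table: pd.DataFrame,
    start_table: pd.DataFrame,
    end_table: pd.DataFrame,
    spec: FeatureSpec = FeatureSpec(),
) -> tuple[PriorityModel, pd.DataFrame, pd.DataFrame]:
    """Full prioritization: assemble -> screen -> standardize -> PCA -> index.

    Returns (model, result table, collinearity report). The model keeps the
    standardization parameters of the screened feature set.
    """
    features = assemble_features(corridor_table, start_table, end_table, spec)
    reduced, report = screen_collinear(
        features, rho_threshold=spec.rho_threshold, drop_preference=spec.drop_preference
    )
    # a variable constant over this corridor set carries no ordering
    # information; drop it rather than fail the standardization
    constant = [c for c in reduced.columns if reduced[c].nunique() <= 1]
    if constant:
        log.warning("dropping constant variable(s) before PCA: %s", constant)
        reduced = reduced.drop(columns=constant)
    if reduced.shape[1] < 2:
        raise ConfigError("fewer than 2 informative variables remain for the PCA")
    z, means, sds = standardize(reduced)
    model = fit_pca(z)
    model.means, model.sds = means, sds
    results = priority_scores(model, z)
    return model, results, report
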