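"""Network-based statistics: edgewise GLM + permutation FWE on component extent.

The method controls family-wise error over the thousands of edges of a
connectome by exploiting their spatial contiguity: an ordinary
least-squares model is fit at every edge (edge weight ~ intercept +
behaviour predictor + nuisance covariates), edges whose predictor
t-statistic exceeds a primary threshold in the hypothesized direction are
kept, and the *extent* (edge count) of each connected supra-threshold
component is compared with the permutation distribution of the maximum
component extent under the null.

Permutation scheme: Freedman-Lane.  The edge weights are residualized on
the nuisance covariates under the reduced model, the residuals are
permuted across subjects, the nuisance fit is added back, and the full
model is refit - the accepted way to permute a GLM in the presence of
nuisance covariates.

Defaults follow common practice for toddler-behaviour connectome studies:
primary threshold t = 3.1, 10,000 permutations, critical FWE p = 0.025
(two behavioural outcomes), plus a sensitivity sweep of the primary
threshold over t = 2.5 ... 3.5 in 0.1 steps sharing one set of
permutations so results differ only by threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Connectome

__all__ = [
    "DesignSpec",
    "EdgewiseGLM",
    "NBSComponent",
    "NBSResult",
    "SensitivitySweep",
    "default_sweep_thresholds",
    "build_edge_matrix",
    "edgewise_glm",
    "extract_components",
    "nbs_test",
    "sensitivity_sweep",
]

T_CAP = 1e6  # sentinel for zero-residual (perfect) fits


def default_sweep_thresholds() -> np.ndarray:
    """Primary-threshold sensitivity grid: 2.5, 2.6, ..., 3.5 (11 values)."""
    return np.round(np.arange(25, 36) / 10.0, 1)


@dataclass(frozen=True)
class DesignSpec:
    """Edgewise GLM design: predictor, nuisance covariates, test settings."""

    predictor: str
    covariates: tuple = ()
    direction: str = "negative"
    t_threshold: float = 3.1
    n_permutations: int = 10_000
    alpha: float = 0.025
    seed: int = 0
    edge_presence_fraction: float = 0.9

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.direction not in ("negative", "positive"):
            raise ValueError("direction must be 'negative' or 'positive'")
        if self.predictor in self.covariates:
            raise ValueError("predictor cannot also be a covariate")


@dataclass
class EdgewiseGLM:
    """Per-edge OLS t-statistics for the predictor, plus the design used."""

    t: np.ndarray                  # (E,) predictor t-statistics
    beta: np.ndarray               # (E,) predictor coefficients
    pairs: np.ndarray              # (E, 2) node indices
    node_ids: list
    df_resid: int
    subjects: list                 # subject ids used, in design order


@dataclass
class NBSComponent:
    nodes: tuple                   # sorted node ids
    edges: tuple                   # sorted (node_a, node_b) id pairs
    extent: int
    p_fwe: float | None = None


@dataclass
class NBSResult:
    glm: EdgewiseGLM
    threshold: float
    direction: str
    components: list
    null_max_extents: np.ndarray
    n_permutations: int
    alpha: float

    @property
    def significant(self) -> list:
        return [c for c in self.components if c.p_fwe is not None and c.p_fwe <= self.alpha]


@dataclass
class SensitivitySweep:
    thresholds: np.ndarray
    results: list = field(default_factory=list)  # one NBSResult per threshold

    def summary(self) -> pd.DataFrame:
        rows = []
        for th, res in zip(self.thresholds, self.results):
            if res.components:
                top = res.components[0]
                rows.append((th, top.extent, top.p_fwe, top.p_fwe <= res.alpha))
            else:
                rows.append((th, 0, np.nan, False))
        return pd.DataFrame(
            rows, columns=["threshold", "max_extent", "p_fwe", "significant"]
        )


def _encode_column(values: pd.Series) -> np.ndarray:
    """Numeric design encoding; two-level string factors become 0/1."""
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        levels = sorted(values.dropna().unique())
        if len(levels) > 2:
            raise ValueError(
                f"cannot encode factor with {len(levels)} levels: {values.name}"
            )
        return values.map({lev: i for i, lev in enumerate(levels)}).to_numpy(float)
    return values.to_numpy(float)


def build_edge_matrix(
    cohort: pd.DataFrame,
    connectomes: list,
    design: DesignSpec,
):
    """Assemble (X, Z, Y, pairs, node_ids, subject ids) for the edgewise GLM.

    Subjects missing any design variable are dropped (listwise deletion).
    The analyzed edges are those with positive weight in at least
    ``design.edge_presence_fraction`` of the retained subjects.
    X is the full design (intercept, predictor, covariates); Z is the
    reduced (nuisance-only) design.
    """
    by_id = {c.subject_id: c for c in connectomes}
    cols = [design.predictor, *design.covariates]
    sub = cohort[cohort["subject_id"].isin(by_id)].copy()
    sub = sub.dropna(subset=[c for c in cols if c in sub.columns])
    missing = [c for c in cols if c not in sub.columns]
    if missing:
        raise ValueError(f"design columns missing from cohort table: {missing}")
    subjects = list(sub["subject_id"])
    n = len(subjects)
    p = 2 + len(design.covariates)
    if n < p + 2:
        raise ValueError(f"too few subjects ({n}) for {p}-column design")

    first = by_id[subjects[0]]
    node_ids = list(first.node_ids)
    nn = len(node_ids)
    iu, ju = np.triu_indices(nn, k=1)
    Y = np.empty((n, iu.size))
    for r, sid in enumerate(subjects):
        Y[r] = by_id[sid].weights[iu, ju]

    present = (Y > 0).mean(axis=0) >= design.edge_presence_fraction
    Y = Y[:, present]
    pairs = np.column_stack([iu[present], ju[present]])

    pred_col = _encode_column(sub[design.predictor])
    cov_cols = [_encode_column(sub[c]) for c in design.covariates]
    # constant covariates are aliased with the intercept; drop them
    cov_cols = [c for c in cov_cols if np.ptp(c) > 0]
    X = np.column_stack([np.ones(n), pred_col] + cov_cols)
    Z = np.delete(X, 1, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return X, Z, Y, pairs, node_ids, subjects


class _OLSEngine:
    """Vectorized OLS over edge columns for a fixed design matrix."""

    def __init__(self, X: np.ndarray, col: int = 1):
        self.X = X
        self.col = col
        self.n, self.p = X.shape
        self.xtx_inv = np.linalg.inv(X.T @ X)
        self.pinv = self.xtx_inv @ X.T
        self.dof = self.n - self.p
        self.var_factor = self.xtx_inv[col, col]

    def fit_t(self, Y: np.ndarray):
        """t and beta of the target column for every edge column of Y."""
        beta = self.pinv @ Y
        resid = Y - self.X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / self.dof
        se = np.sqrt(sigma2 * self.var_factor)
        b = beta[self.col]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.sign(b) * T_CAP)
        return np.clip(t, -T_CAP, T_CAP), b


def _fit_t(X: np.ndarray, Y: np.ndarray, col: int = 1):
    return _OLSEngine(X, col).fit_t(Y)


def edgewise_glm(
    cohort: pd.DataFrame, connectomes: list, design: DesignSpec
) -> EdgewiseGLM:
    """OLS of each analyzed edge weight on the design; predictor t per edge."""
    X, _, Y, pairs, node_ids, subjects = build_edge_matrix(cohort, connectomes, design)
    t, beta = _fit_t(X, Y)
    return EdgewiseGLM(
        t=t, beta=beta, pairs=pairs, node_ids=node_ids,
        df_resid=X.shape[0] - X.shape[1], subjects=subjects,
    )


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[x] = p
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _directed_t(t: np.ndarray, direction: str) -> np.ndarray:
    return -t if direction == "negative" else t


def _component_extents(td: np.ndarray, pairs: np.ndarray, threshold: float):
    """Connected supra-threshold components as lists of edge indices."""
    supra = np.flatnonzero(td > threshold)
    if supra.size == 0:
        return []
    uf = _UnionFind()
    for k in supra:
        uf.union(int(pairs[k, 0]), int(pairs[k, 1]))
    groups = {}
    for k in supra:
        groups.setdefault(uf.find(int(pairs[k, 0])), []).append(int(k))
    return list(groups.values())


def _max_extent(td: np.ndarray, pairs: np.ndarray, threshold: float) -> int:
    comps = _component_extents(td, pairs, threshold)
    return max((len(c) for c in comps), default=0)


def extract_components(
    edge_t: np.ndarray,
    pairs: np.ndarray,
    node_ids: list,
    threshold: float,
    direction: str = "negative",
) -> list:
    """Maximal connected components of supra-threshold edges.

    Ordered by descending extent, ties by lexicographically smallest node
    set, so the output is deterministic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    td = _directed_t(np.asarray(edge_t, float), direction)
    comps = []
    for edge_idx in _component_extents(td, pairs, threshold):
        epairs = sorted(
            tuple(sorted((node_ids[pairs[k, 0]], node_ids[pairs[k, 1]])))
            for k in edge_idx
        )
        nodes = tuple(sorted({n for e in epairs for n in e}))
        comps.append(NBSComponent(nodes=nodes, edges=tuple(epairs), extent=len(epairs)))
    comps.sort(key=lambda c: (-c.extent, c.nodes))
    return comps


def nbs_test(
    cohort: pd.DataFrame,
    connectomes: list,
    design: DesignSpec,
    thresholds=None,
) -> "NBSResult | SensitivitySweep":
    """Run the full permutation test; FWE p-values on component extent.

    With ``thresholds`` given, the same permutations score every
    threshold and a :class:`SensitivitySweep` is returned; otherwise a
    single :class:`NBSResult` at ``design.t_threshold``.
    """
    X, Z, Y, pairs, node_ids, subjects = build_edge_matrix(cohort, connectomes, design)
    n = X.shape[0]
    t_obs, beta = _fit_t(X, Y)
    glm = EdgewiseGLM(
        t=t_obs, beta=beta, pairs=pairs, node_ids=node_ids,
        df_resid=n - X.shape[1], subjects=subjects,
    )
    td_obs = _directed_t(t_obs, design.direction)

    th_list = (
        [float(design.t_threshold)] if thresholds is None
        else [float(t) for t in thresholds]
    )

    # Freedman-Lane: permute reduced-model residuals, add the nuisance fit back
    gamma = np.linalg.lstsq(Z, Y, rcond=None)[0]
    fitted_z = Z @ gamma
    resid_z = Y - fitted_z

    engine = _OLSEngine(X)
    rng = np.random.default_rng(design.seed)
    null_max = np.zeros((len(th_list), design.n_permutations), dtype=np.int64)
    for b in range(design.n_permutations):
        perm = rng.permutation(n)
        t_perm, _ = engine.fit_t(resid_z[perm] + fitted_z)
        td = _directed_t(t_perm, design.direction)
        for ti, th in enumerate(th_list):
            null_max[ti, b] = _max_extent(td, pairs, th)

    def result_at(ti: int, th: float) -> NBSResult:
        comps = extract_components(t_obs, pairs, node_ids, th, design.direction)
        for c in comps:
            c.p_fwe = float(
                (1 + (null_max[ti] >= c.extent).sum()) / (1 + design.n_permutations)
            )
        return NBSResult(
            glm=glm, threshold=th, direction=design.direction, components=comps,
            null_max_extents=null_max[ti].copy(),
            n_permutations=design.n_permutations, alpha=design.alpha,
        )

    if thresholds is None:
        return result_at(0, th_list[0])
    sweep = SensitivitySweep(thresholds=np.asarray(th_list))
    sweep.results = [result_at(ti, th) for ti, th in enumerate(th_list)]
    return sweep


def sensitivity_sweep(
    cohort: pd.DataFrame,
    connectomes: list,
    design: DesignSpec,
    thresholds=None,
) -> SensitivitySweep:
    """NBS at each primary threshold, sharing one permutation stream."""
    th = default_sweep_thresholds() if thresholds is None else np.asarray(thresholds, float)
    if th.size == 0:
        raise ValueError("thresholds must be nonempty")
    return nbs_test(cohort, connectomes, design, thresholds=th)


def edge_t_table(glm: EdgewiseGLM) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_a": [glm.node_ids[i] for i in glm.pairs[:, 0]],
            "node_b": [glm.node_ids[j] for j in glm.pairs[:, 1]],
            "beta": glm.beta,
            "t": glm.t,
        }
    )


def component_table(result: NBSResult) -> pd.DataFrame:
    t_by_pair = {
        tuple(sorted((result.glm.node_ids[i], result.glm.node_ids[j]))): t
        for (i, j), t in zip(result.glm.pairs, result.glm.t)
    }
    rows = []
    for ci, comp in enumerate(result.components):
        for a, b in comp.edges:
            rows.append((ci, a, b, t_by_pair[(a, b)], comp.extent, comp.p_fwe))
    return pd.DataFrame(
        rows,
        columns=["component_id", "node_a", "node_b", "t", "extent", "p_fwe"],
    )
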