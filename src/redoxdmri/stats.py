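"""Cohort-level statistics: delay filtering, robust regression, group
tests, HC-median ratio split, and voxelwise permutation inference with
threshold-free cluster enhancement (TFCE) and FDR over the skeleton.

The voxelwise engine tests one regression term per voxel of a skeleton
metric (a marker slope, a slope-by-group contrast, or a three-way
marker x ratio-class x group interaction), always adjusting for sex,
centred age, centred age squared and the MRI-blood delay.  Inference is by
Freedman-Lane permutation of reduced-model residuals, TFCE of the |t| map
over the skeleton's 26-connectivity graph, per-voxel permutation p-values
(b+1)/(n_perm+1), and Benjamini-Hochberg FDR across skeleton voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io import CohortTable
from .skeleton import SkeletonDataset

__all__ = [
    "filter_delay",
    "robust_lm",
    "RobustLMResult",
    "welch_t",
    "chi_square_2x2",
    "median_split",
    "tfce",
    "ModelSpec",
    "AssociationResult",
    "VoxelwiseAssociation",
    "voxelwise_association",
    "huber_irls_multi",
]

MAX_DELAY_DEFAULT = 60.0  # days
TFCE_E, TFCE_H, TFCE_STEPS = 0.5, 2.0, 100
HUBER_C = 1.345


# ---------------------------------------------------------------------------
# scalar-level operations
# ---------------------------------------------------------------------------


def filter_delay(cohort: CohortTable, max_delay: float = MAX_DELAY_DEFAULT) -> CohortTable:
    """Drop subjects whose MRI-to-blood-draw delay exceeds ``max_delay``.

    The boundary is inclusive: 'larger than 60 days' excludes only strictly
    greater delays, so delay == max_delay is retained.
    """
    import logging

    keep = cohort.df["delay"].to_numpy() <= max_delay
    n_out = int((~keep).sum())
    if n_out:
        logging.getLogger("redoxdmri").warning(
            "excluding %d subjects with delay > %g days", n_out, max_delay
        )
    if not keep.any():
        logging.getLogger("redoxdmri").warning("delay filter removed every subject")
    return cohort.subset(keep)


@dataclass
class RobustLMResult:
    params: np.ndarray
    bse: np.ndarray
    scale: float
    weights: np.ndarray
    converged: bool


def _name_dependent_columns(X: np.ndarray) -> list[int]:
    from scipy.linalg import qr

    _, r, piv = qr(X, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return sorted(piv[rank:].tolist())


def robust_lm(y: np.ndarray, X: np.ndarray, tuning_const: float = HUBER_C) -> RobustLMResult:
    """Huber M-estimation (c = 1.345 by default, MAD scale) via IRLS.

    Backed by statsmodels' RLM; raises on rank-deficient designs (naming
    the dependent columns) and on non-convergence.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) <= X.shape[1]:
        raise ValueError(f"n = {len(y)} observations <= {X.shape[1]} columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        dep = _name_dependent_columns(X)
        raise ValueError(f"design matrix is rank deficient; dependent column(s): {dep}")
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=tuning_const))
    res = model.fit(scale_est="mad", maxiter=200, tol=1e-8)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise RuntimeError(f"IRLS failed to converge in {200} iterations (fit_history kept)")
    return RobustLMResult(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        scale=float(res.scale),
        weights=np.asarray(res.weights),
        converged=converged,
    )


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    from scipy import stats as sps

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups; Welch statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    df = (va / len(a) + vb / len(b)) ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction, df = 1."""
    from scipy.stats import chi2_contingency

    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = chi2_contingency(counts, correction=False)
    return float(chi2), int(dof), float(p)


def median_split(cohort: CohortTable) -> np.ndarray:
    """Classify every subject as 'low' or 'high' GPx/GR ratio relative to
    the median ratio of the HC group (ties at the threshold go to 'high')."""
    hc = cohort.df["group"] == "HC"
    if not hc.any():
        raise ValueError("median split needs at least one HC subject")
    threshold = float(np.median(cohort.ratio[hc.to_numpy()]))
    return np.where(cohort.ratio.to_numpy() < threshold, "low", "high")


# ---------------------------------------------------------------------------
# vectorized Huber IRLS across many responses (reported slopes)
# ---------------------------------------------------------------------------


def huber_irls_multi(Y: np.ndarray, X: np.ndarray, c: float = HUBER_C,
                     tol: float = 1e-8, maxiter: int = 200) -> np.ndarray:
    """Huber M-estimates for many responses sharing one design.

    Y is (n, V); returns coefficients (k, V).  MAD scale per response,
    IRLS with Huber weights — the vectorized counterpart of
    :func:`robust_lm` used for per-voxel reported slopes.
    """
    n, V = Y.shape
    k = X.shape[1]
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]  # (k, V) OLS start
    for _ in range(maxiter):
        resid = Y - X @ beta
        # zero-centred MAD, matching the single-response IRLS convention
        scale = np.median(np.abs(resid), axis=0) / 0.6745
        scale = np.maximum(scale, 1e-12)
        u = resid / scale
        w = np.minimum(1.0, c / np.maximum(np.abs(u), 1e-12))  # Huber weights
        XtWX = np.einsum("ni,nv,nj->vij", X, w, X, optimize=True)
        XtWy = np.einsum("ni,nv,nv->vi", X, w, Y, optimize=True)
        new = np.linalg.solve(XtWX, XtWy[..., None])[..., 0].T  # (k, V)
        if np.max(np.abs(new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    return beta


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


@njit(cache=True)
def _find(parent, v):
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        nxt = parent[v]
        parent[v] = root
        v = nxt
    return root


@njit(cache=True)
def _tfce_kernel(stat, indptr, indices, E, H, n_steps):
    V = stat.size
    out = np.zeros(V)
    hmax = stat.max()
    if hmax <= 0.0:
        return out
    dh = hmax / n_steps
    order = np.argsort(stat)[::-1]
    parent = np.empty(V, dtype=np.int64)
    size = np.zeros(V, dtype=np.int64)
    active = np.zeros(V, dtype=np.bool_)
    act_list = np.empty(V, dtype=np.int64)
    n_act = 0
    pos = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        while pos < V and stat[order[pos]] >= h:
            v = order[pos]
            parent[v] = v
            size[v] = 1
            active[v] = True
            act_list[n_act] = v
            n_act += 1
            for t in range(indptr[v], indptr[v + 1]):
                w = indices[t]
                if active[w]:
                    rv = _find(parent, v)
                    rw = _find(parent, w)
                    if rv != rw:
                        if size[rv] < size[rw]:
                            rv, rw = rw, rv
                        parent[rw] = rv
                        size[rv] += size[rw]
            pos += 1
        hh = h**H * dh
        for t in range(n_act):
            v = act_list[t]
            out[v] += size[_find(parent, v)] ** E * hh
    return out


def tfce(stat_map: np.ndarray, indptr: np.ndarray, indices: np.ndarray,
         E: float = TFCE_E, H: float = TFCE_H, n_steps: int = TFCE_STEPS) -> np.ndarray:
    """Threshold-free cluster enhancement over a skeleton adjacency graph.

    TFCE(v) = sum_h e(h, v)^E h^H dh, where e(h, v) is the size of the
    suprathreshold (stat >= h) connected component containing v.  Only
    positive statistic values are enhanced; the output is zero wherever
    stat <= 0.  Defaults E = 0.5, H = 2, 100 integration steps.
    """
    stat_map = np.ascontiguousarray(stat_map, dtype=np.float64)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("statistic map contains non-finite values")
    if len(indices) == 0:
        raise ValueError("empty adjacency: skeleton has no edges")
    return _tfce_kernel(
        stat_map, np.ascontiguousarray(indptr, dtype=np.int64),
        np.ascontiguousarray(indices, dtype=np.int64), float(E), float(H), int(n_steps),
    )


# ---------------------------------------------------------------------------
# voxelwise association
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """One voxelwise association analysis.

    predictor: 'gpx' | 'gr' | 'ratio' (GPx/GR).  The covariates are fixed:
    sex, centred age, centred age squared, and delay.  interaction selects
    the tested term: None tests the predictor slope itself; 'group' tests
    the slope-by-group contrast; 'ratio_class:group' tests the three-way
    predictor x ratio-class x group interaction.  groups restricts the
    subject subset ('all', 'HC', 'PT').
    """

    response: str = "MK"
    predictor: str = "gr"
    interaction: str | None = None
    groups: str = "all"

    def __post_init__(self):
        if self.predictor not in {"gpx", "gr", "ratio"}:
            raise ValueError("predictor must be gpx, gr or ratio")
        if self.interaction not in {None, "group", "ratio_class", "ratio_class:group"}:
            raise ValueError(f"unknown interaction {self.interaction!r}")
        if self.groups not in {"all", "HC", "PT"}:
            raise ValueError("groups must be all, HC or PT")
        if self.interaction in {"group", "ratio_class:group"} and self.groups != "all":
            raise ValueError("group interactions need both groups in the model")


def build_design(cohort: CohortTable, spec: ModelSpec, ratio_class: np.ndarray | None = None):
    """Design matrix, column names and tested-term index for a ModelSpec.

    Age is centred before squaring to limit collinearity; the predictor is
    centred so interaction terms are interpretable.
    """
    df = cohort.df
    pred = cohort.ratio.to_numpy() if spec.predictor == "ratio" else df[spec.predictor].to_numpy()
    pred = pred - pred.mean()
    age_c = df["age"].to_numpy() - df["age"].to_numpy().mean()
    sex = (df["sex"] == "F").to_numpy().astype(float)
    delay = df["delay"].to_numpy()
    cols = [np.ones(len(df)), sex, age_c, age_c**2, delay]
    names = ["intercept", "sex", "age_c", "age_c2", "delay"]

    if spec.interaction is None:
        cols += [pred]
        names += [spec.predictor]
    elif spec.interaction == "group":
        grp = (df["group"] == "PT").to_numpy().astype(float)
        cols += [grp, pred, pred * grp]
        names += ["group", spec.predictor, f"{spec.predictor}:group"]
    elif spec.interaction == "ratio_class":
        if ratio_class is None:
            raise ValueError("ratio_class labels required")
        low = (ratio_class == "low").astype(float)
        cols += [low, pred, pred * low]
        names += ["low_ratio", spec.predictor, f"{spec.predictor}:low_ratio"]
    else:  # ratio_class:group three-way
        if ratio_class is None:
            raise ValueError("ratio_class labels required")
        grp = (df["group"] == "PT").to_numpy().astype(float)
        low = (ratio_class == "low").astype(float)
        cols += [grp, low, grp * low, pred, pred * grp, pred * low, pred * grp * low]
        names += ["group", "low_ratio", "group:low_ratio", spec.predictor,
                  f"{spec.predictor}:group", f"{spec.predictor}:low_ratio",
                  f"{spec.predictor}:group:low_ratio"]
    X = np.column_stack(cols)
    return X, names, len(names) - 1


def _ols_tmaps(Y: np.ndarray, X: np.ndarray, j: int, pinvX: np.ndarray, xtx_inv_jj: float) -> np.ndarray:
    n, k = X.shape
    beta = pinvX @ Y  # (k, V)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / (n - k)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_jj, 1e-300))
    return beta[j] / se


@dataclass
class AssociationResult:
    """Voxelwise association maps with permutation/TFCE/FDR inference."""

    beta_map: np.ndarray
    t_map: np.ndarray
    tfce_map: np.ndarray
    p_perm_map: np.ndarray
    p_fdr_map: np.ndarray
    p_fwe_map: np.ndarray  # from the max-TFCE permutation null (family-wise)
    significant: np.ndarray
    clusters: list  # dicts: voxels, size, peak_t
    n_perm: int
    seed: int
    alpha: float
    term: str
    spec: ModelSpec | None = None

    def summary(self) -> str:
        lines = [
            f"Voxelwise association: term {self.term!r}, {len(self.t_map)} voxels",
            f"  permutations: {self.n_perm} (seed {self.seed}), alpha = {self.alpha}",
            f"  significant voxels (FDR): {int(self.significant.sum())}",
            f"  clusters: {len(self.clusters)}"
            + (f", largest {max(c['size'] for c in self.clusters)} voxels" if self.clusters else ""),
            f"  peak |t| = {np.max(np.abs(self.t_map)):.3f}",
        ]
        return "\n".join(lines)


def _connected_components(voxels: np.ndarray, indptr, indices) -> list[np.ndarray]:
    in_set = np.zeros(indptr.size - 1, dtype=bool)
    in_set[voxels] = True
    seen = np.zeros_like(in_set)
    comps = []
    for v in voxels:
        if seen[v]:
            continue
        comp = [v]
        seen[v] = True
        queue = [v]
        while queue:
            u = queue.pop()
            for w in indices[indptr[u]:indptr[u + 1]]:
                if in_set[w] and not seen[w]:
                    seen[w] = True
                    comp.append(w)
                    queue.append(w)
        comps.append(np.array(sorted(comp)))
    return comps


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class VoxelwiseAssociation:
    """Voxelwise marker-microstructure association model.

    Parameters
    ----------
    skeleton : SkeletonDataset
        Harmonized subjects x voxels metric matrices with adjacency.
    cohort : CohortTable
        Already delay-filtered; subject order must match the skeleton.
    spec : ModelSpec
        Response metric, predictor marker, tested term, subject subset.

    ``fit(n_perm, alpha, seed)`` runs Freedman-Lane permutations, TFCE and
    BH-FDR, and returns an :class:`AssociationResult`.  Reported slopes
    (beta_map) come from vectorized Huber IRLS; the permuted statistic is
    the OLS t of the tested term.
    """

    def __init__(self, skeleton: SkeletonDataset, cohort: CohortTable, spec: ModelSpec):
        if list(cohort.df["subject_id"]) != list(skeleton.subjects):
            raise ValueError("cohort subjects do not match skeleton subjects (order included)")
        if spec.response not in skeleton.metrics:
            raise ValueError(f"metric {spec.response!r} absent from skeleton dataset")
        self.spec = spec
        ratio_class = median_split(cohort) if spec.interaction in {"ratio_class", "ratio_class:group"} else None
        if spec.groups != "all":
            keep = (cohort.df["group"] == spec.groups).to_numpy()
            cohort = cohort.subset(keep)
            skeleton = skeleton.subset_subjects(keep)
            if ratio_class is not None:
                ratio_class = ratio_class[keep]
        self.cohort = cohort
        self.skeleton = skeleton
        self.X, self.names, self.j = build_design(cohort, spec, ratio_class)
        n, k = self.X.shape
        if n <= k:
            raise ValueError("fewer subjects than design columns")
        if np.linalg.matrix_rank(self.X) < k:
            dep = _name_dependent_columns(self.X)
            raise ValueError(
                f"tested term collinear with covariates; dependent columns "
                f"{[self.names[i] for i in dep]}"
            )

    def fit(self, n_perm: int = 5000, alpha: float = 0.05, seed: int = 0,
            compute_beta: bool = True) -> AssociationResult:
        import logging

        if n_perm < 100:
            logging.getLogger("redoxdmri").warning(
                "n_perm = %d is too small for stable inference", n_perm
            )
        X, j = self.X, self.j
        n, k = X.shape
        tmpl = self.skeleton.template
        Y = np.ascontiguousarray(self.skeleton.metrics[self.spec.response])  # (n, V)
        pinvX = np.linalg.pinv(X)
        xtx_inv_jj = float(np.linalg.inv(X.T @ X)[j, j])
        t_obs = _ols_tmaps(Y, X, j, pinvX, xtx_inv_jj)
        tfce_obs = tfce(np.abs(t_obs), tmpl.indptr, tmpl.indices)

        # Freedman-Lane: permute residuals of the reduced model
        Z = np.delete(X, j, axis=1)
        pinvZ = np.linalg.pinv(Z)
        fitted_red = Z @ (pinvZ @ Y)
        R = Y - fitted_red
        rng = np.random.default_rng(seed)
        exceed = np.zeros(Y.shape[1], dtype=np.int64)
        max_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            Ystar = fitted_red + R[perm]
            t_star = _ols_tmaps(Ystar, X, j, pinvX, xtx_inv_jj)
            tfce_star = tfce(np.abs(t_star), tmpl.indptr, tmpl.indices)
            exceed += tfce_star >= tfce_obs
            max_null[b] = tfce_star.max()
        p_perm = (exceed + 1.0) / (n_perm + 1.0)
        p_fdr = _bh_fdr(p_perm)
        # family-wise p from the null of the maximum TFCE (exact under
        # permutation exchangeability)
        max_sorted = np.sort(max_null)
        n_ge = n_perm - np.searchsorted(max_sorted, tfce_obs, side="left")
        p_fwe = (n_ge + 1.0) / (n_perm + 1.0)
        significant = p_fdr <= alpha

        # robust (Huber) slopes are the reported effect sizes; the permuted
        # statistic above stays OLS for tractability
        beta = huber_irls_multi(Y, X)[j] if compute_beta else np.full(Y.shape[1], np.nan)
        comps = _connected_components(np.flatnonzero(significant), tmpl.indptr, tmpl.indices)
        clusters = [
            dict(voxels=c, size=int(len(c)), peak_t=float(np.max(np.abs(t_obs[c])))) for c in comps
        ]
        clusters.sort(key=lambda c: -c["size"])
        return AssociationResult(
            beta_map=beta, t_map=t_obs, tfce_map=tfce_obs, p_perm_map=p_perm,
            p_fdr_map=p_fdr, p_fwe_map=p_fwe, significant=significant, clusters=clusters,
            n_perm=n_perm, seed=seed, alpha=alpha, term=self.names[j], spec=self.spec,
        )


def voxelwise_association(skeleton: SkeletonDataset, cohort: CohortTable, spec: ModelSpec,
                          alpha: float = 0.05, n_perm: int = 5000, seed: int = 0) -> AssociationResult:
    """Functional wrapper over :class:`VoxelwiseAssociation`."""
    return VoxelwiseAssociation(skeleton, cohort, spec).fit(n_perm=n_perm, alpha=alpha, seed=seed)
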