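"""Node-wise group inference on scalp maps.

Implements unequal-variance (Aspin-Welch) t statistics for a contrast
in a linear model with covariates, Freedman-Lane permutation inference
with max-statistic family-wise error (FWE) correction, node-wise
Hedge's g effect-size maps with bootstrap CIs, and peak localization.

The Freedman-Lane scheme fits the nuisance-only model, permutes its
residuals, adds back the nuisance fit, and recomputes the contrast
statistic, so the permutation distribution respects the covariates.
The observed labelling counts as one permutation; the smallest
achievable p is 1 / (1 + n_perm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np

from .montage import MontageLayout
from .scalpmap import ScalpMap, subject_maps_matrix


@dataclass(frozen=True)
class PermutationSpec:
    n_perm: int = 10000
    seed: int = 0
    fwe_alpha: float = 0.05
    tail: str = "one"  # "one": contrast direction; "two": |t|

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")


@dataclass
class PermResult:
    """Observed statistics and permutation p-values, node-wise."""

    t: np.ndarray  # (v,)
    df: np.ndarray  # (v,) Welch-Satterthwaite dfs
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    null_max_distribution: np.ndarray  # (n_perm,)
    n_perm: int
    tail: str
    peak_index: int
    peak_stat: float
    peak_df: float
    peak_xy: np.ndarray | None = None
    peak_electrode: str | None = None
    template: ScalpMap | None = field(default=None, repr=False)

    def t_map(self) -> ScalpMap:
        return self._as_map(self.t)

    def p_fwe_map(self) -> ScalpMap:
        return self._as_map(self.p_fwe)

    def p_uncorrected_map(self) -> ScalpMap:
        return self._as_map(self.p_uncorrected)

    def _as_map(self, values: np.ndarray) -> ScalpMap:
        if self.template is None:
            raise ValueError("result was computed from a plain matrix; "
                             "no grid template available")
        return self.template.with_values(values)


def _prepare(Y, design, contrast):
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("Y must be (subjects, nodes) and design rows "
                         "must match subjects")
    if c.shape != (X.shape[1],):
        raise ValueError("contrast length must equal design columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return Y, X, c


def _group_masks(variance_groups, n) -> list[np.ndarray]:
    if variance_groups is None:
        return [np.ones(n, dtype=bool)]
    vg = np.asarray(variance_groups)
    if vg.shape != (n,):
        raise ValueError("variance_groups must have one label per subject")
    masks = [vg == g for g in np.unique(vg)]
    for m in masks:
        if m.sum() < 2:
            raise ValueError("every variance group needs >= 2 subjects")
    return masks


class _WelchEngine:
    """Precomputed pieces for repeated contrast-t evaluation on (n, v) data.

    Per variance group g the contrast variance contribution is
    a_g * s2_g with a_g = c A X_g' X_g A c' (A = (X'X)^-1) and s2_g the
    group residual variance on df_g = n_g - tr(H_gg) degrees of freedom;
    Welch-Satterthwaite combines the per-group contributions into an
    effective df.  With a single variance group this reduces to the
    ordinary OLS t with df = n - k.
    """

    def __init__(self, X: np.ndarray, c: np.ndarray, masks: list[np.ndarray]):
        self.X = X
        self.c = c
        self.masks = masks
        A = np.linalg.inv(X.T @ X)
        self.pinv = A @ X.T
        lev = np.einsum("ij,jk,ik->i", X, A, X)  # leverages h_ii
        self.a = np.empty(len(masks))
        self.dfg = np.empty(len(masks))
        for j, m in enumerate(masks):
            Xg = X[m]
            self.a[j] = float(c @ A @ Xg.T @ Xg @ A @ c)
            self.dfg[j] = m.sum() - lev[m].sum()
            if self.dfg[j] <= 0:
                raise ValueError("non-positive residual df in a variance "
                                 "group; model too rich for group size")

    def t_and_df(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = self.pinv @ Y
        resid = Y - self.X @ beta
        effect = self.c @ beta  # (v,)
        contrib = np.stack([
            self.a[j] * (resid[m] ** 2).sum(axis=0) / self.dfg[j]
            for j, m in enumerate(self.masks)])  # (n_groups, v)
        var = contrib.sum(axis=0)
        var = np.where(var > 0, var, np.nan)
        t = effect / np.sqrt(var)
        df = var ** 2 / (contrib ** 2 / self.dfg[:, None]).sum(axis=0)
        return t, df


def _coerce_maps(maps):
    if isinstance(maps, np.ndarray):
        return maps, None
    Y = subject_maps_matrix(list(maps))
    return Y, maps[0]


def voxel_t(Y, design, contrast, variance_groups=None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Aspin-Welch contrast t and Welch-Satterthwaite df at every node."""
    Y, X, c = _prepare(Y, design, contrast)
    eng = _WelchEngine(X, c, _group_masks(variance_groups, Y.shape[0]))
    return eng.t_and_df(Y)


def voxel_t_map(maps, design, contrast, variance_groups=None
                ) -> tuple[ScalpMap, np.ndarray]:
    """As :func:`voxel_t` for a list of subject ScalpMaps."""
    Y, template = _coerce_maps(maps)
    t, df = voxel_t(Y, design, contrast, variance_groups)
    if template is None:
        raise ValueError("voxel_t_map requires ScalpMaps; use voxel_t for "
                         "plain matrices")
    return template.with_values(t), df


def nearest_electrode(xy, layout: MontageLayout) -> str:
    """Label of the Euclidean-nearest electrode; ties broken alphabetically."""
    xy = np.asarray(xy, dtype=float)
    d = np.linalg.norm(layout.xy - xy, axis=1)
    best = d.min()
    candidates = [layout.labels[i] for i in np.flatnonzero(d <= best + 1e-12)]
    return min(candidates)


def _permutation_stream(n: int, spec: PermutationSpec):
    """Permutations to evaluate; exhaustive (identity excluded) for small n.

    The observed labelling is accounted for by the +1/+1 in the p-value
    formula, so the identity is never drawn explicitly.
    """
    n_distinct = math.factorial(n)
    if n <= 8 or spec.n_perm >= n_distinct - 1:
        if spec.n_perm > n_distinct - 1:
            warnings.warn(
                f"n_perm = {spec.n_perm} meets or exceeds the {n_distinct} "
                "distinct permutations; enumerating exhaustively",
                stacklevel=3)
        gen = (np.array(p) for i, p in
               enumerate(iter_permutations(range(n))) if i > 0)
        return gen, n_distinct - 1
    rng = np.random.default_rng(spec.seed)
    return (rng.permutation(n) for _ in range(spec.n_perm)), spec.n_perm


def freedman_lane(maps, design, contrast, spec: PermutationSpec,
                  variance_groups=None, effect_columns=None,
                  layout: MontageLayout | None = None) -> PermResult:
    """Freedman-Lane permutation test with max-statistic FWE correction.

    ``maps`` is a list of subject ScalpMaps (shared grid/mask) or a
    plain (subjects, nodes) matrix.  The effect-of-interest columns of
    the design default to the support of the contrast; the remaining
    columns are nuisance.  With no nuisance columns the scheme reduces
    to plain label permutation.

    p_uncorrected(node) = (1 + #{perm t >= observed t}) / (1 + n_perm);
    p_fwe uses the permutation distribution of the max statistic over
    nodes.  Deterministic under ``spec.seed``.
    """
    Y, template = _coerce_maps(maps)
    Y, X, c = _prepare(Y, design, contrast)
    n = Y.shape[0]
    if effect_columns is None:
        effect_columns = np.flatnonzero(c != 0)
    effect_columns = np.asarray(effect_columns)
    nuisance = np.setdiff1d(np.arange(X.shape[1]), effect_columns)

    masks = _group_masks(variance_groups, n)
    eng = _WelchEngine(X, c, masks)
    t_obs, df = eng.t_and_df(Y)
    stat_obs = np.abs(t_obs) if spec.tail == "two" else t_obs

    if nuisance.size:
        Z = X[:, nuisance]
        Zg = Z @ np.linalg.pinv(Z) @ Y  # nuisance fit
        resid = Y - Zg
    else:
        Zg = np.zeros_like(Y)
        resid = Y

    perms, n_perm_eff = _permutation_stream(n, spec)
    exceed = np.zeros(Y.shape[1])
    max_null = np.empty(n_perm_eff)
    for i, perm in enumerate(perms):
        t_p, _ = eng.t_and_df(Zg + resid[perm])
        s = np.abs(t_p) if spec.tail == "two" else t_p
        exceed += s >= stat_obs - 1e-12
        max_null[i] = s.max()

    p_unc = (1.0 + exceed) / (1.0 + n_perm_eff)
    p_fwe = (1.0 + (max_null[:, None] >=
                    stat_obs[None, :] - 1e-12).sum(axis=0)) / (1.0 + n_perm_eff)

    peak = int(np.nanargmax(stat_obs))
    peak_xy = peak_label = None
    if template is not None:
        peak_xy = template.node_xy()[peak]
        if layout is not None:
            peak_label = nearest_electrode(peak_xy, layout)
    return PermResult(
        t=t_obs, df=df, p_uncorrected=p_unc, p_fwe=p_fwe,
        null_max_distribution=max_null, n_perm=n_perm_eff, tail=spec.tail,
        peak_index=peak, peak_stat=float(t_obs[peak]),
        peak_df=float(df[peak]), peak_xy=peak_xy, peak_electrode=peak_label,
        template=template)


def effect_size_map(maps_a, maps_b, n_boot: int = 5000, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray, ScalpMap | None]:
    """Node-wise Hedge's g (group a minus group b) with bootstrap 95% CIs.

    Bootstrap resamples subjects within each group (never nodes).
    Nodes with zero pooled variance are flagged NaN.  Returns
    (g, ci) with ci of shape (2, nodes), plus the grid template when
    ScalpMaps were given.
    """
    Ya, template = _coerce_maps(maps_a)
    Yb, _ = _coerce_maps(maps_b)
    if Ya.shape[0] < 2 or Yb.shape[0] < 2:
        raise ValueError(">= 2 subjects per group required")
    if Ya.shape[1] != Yb.shape[1]:
        raise ValueError("groups must share the node set")

    def g_stat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        na, nb = a.shape[0], b.shape[0]
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        J = 1 - 3 / (4 * (na + nb) - 9)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (a.mean(axis=0) - b.mean(axis=0)) / sp * J
        return np.where(sp > 0, g, np.nan)

    g = g_stat(Ya, Yb)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, Ya.shape[1]))
    for i in range(n_boot):
        boots[i] = g_stat(Ya[rng.integers(0, Ya.shape[0], Ya.shape[0])],
                          Yb[rng.integers(0, Yb.shape[0], Yb.shape[0])])
    ci = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return g, ci, template
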