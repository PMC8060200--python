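"""Two-step cluster-based permutation comparison of trial x frequency maps.

The procedure tests whether two groups of subjects (or two paired conditions
of the same subjects) differ anywhere in their trial x frequency power maps,
while controlling the family-wise error over the tens of thousands of bins:

Step 1 (bin level).  A t statistic is computed independently for each bin —
the unequal-variance two-sample t for independent groups, the paired t on
per-subject differences for paired designs.  Its null distribution at each
bin is built by relabeling: group labels are permuted (independent design) or
condition labels are flipped within random subsets of pairs (paired design),
``n_shuffle`` times.  Bins whose two-sided permutation p falls below
``alpha_bin`` (default 0.001) are marked significant.

Step 2 (cluster level).  Contiguous significant bins of like t-sign are
joined into clusters (4-connectivity on the trial x frequency grid by
default) and each cluster's mass — the sum of its t values — is compared with
a Monte Carlo reference distribution: every shuffled map is thresholded the
same way, clustered the same way, and contributes its maximum |mass|.  A
cluster is significant when its |mass| is rarely reached by that max-statistic
null (``alpha_cluster``, default 0.05).

p-values use the add-one estimator p = (1 + #{extreme}) / (1 + n_shuffle), so
no p is ever zero.  When the design admits no more relabelings than
``n_shuffle`` the full set is enumerated instead and p is the exact
proportion #{|t*| >= |t|} / N (the identity relabeling included).

Defaults (n_shuffle=5000, alpha_bin=0.001, alpha_cluster=0.05) follow common
practice for cluster-corrected map comparisons.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tft import TFTMap

__all__ = [
    "BinTestResult",
    "Cluster",
    "ClusterPermutationTest",
    "ClusterPermutationResults",
    "binwise_permutation_test",
    "form_clusters",
    "cluster_permutation_test",
    "report",
]

logger = logging.getLogger(__name__)

DEFAULT_N_SHUFFLE = 5000
DEFAULT_ALPHA_BIN = 0.001
DEFAULT_ALPHA_CLUSTER = 0.05

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


# ---------------------------------------------------------------------------
# result containers


@dataclass
class BinTestResult:
    """Bin-level permutation test output.

    ``t_map`` holds the observed statistic per bin, ``p_map`` the two-sided
    permutation p, ``sig_mask`` marks p < alpha_bin.
    """

    t_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    alpha_bin: float
    n_shuffle: int
    exact: bool = False


@dataclass
class Cluster:
    """A contiguous set of significant bins sharing one t-sign."""

    bins: np.ndarray  # (n_bins, 2) array of (trial, frequency) indices
    mass: float  # sum of t values over member bins
    sign: int  # +1 or -1
    p_value: float = float("nan")

    @property
    def n_bins(self) -> int:
        return int(self.bins.shape[0])

    @property
    def trial_range(self) -> tuple[int, int]:
        """Inclusive (min, max) trial extent."""
        return int(self.bins[:, 0].min()), int(self.bins[:, 0].max())

    @property
    def freq_range(self) -> tuple[int, int]:
        """Inclusive (min, max) frequency-index extent."""
        return int(self.bins[:, 1].min()), int(self.bins[:, 1].max())

    def trials(self) -> np.ndarray:
        """Sorted unique trial indices the cluster touches."""
        return np.unique(self.bins[:, 0])


# ---------------------------------------------------------------------------
# relabeling schemes


def _enumerate_independent(n_a: int, n_b: int) -> np.ndarray | None:
    """All distinct assignments of n_a labels among n_a + n_b subjects.

    Returns an (N, n_a) index array (members of group A per relabeling) or
    None if the count exceeds the enumeration cap implied by the caller.
    """
    n = n_a + n_b
    count = 1
    for i in range(1, n_a + 1):  # C(n, n_a) without overflow surprises
        count = count * (n - n_a + i) // i
    idx = np.array(list(itertools.combinations(range(n), n_a)), dtype=np.intp)
    assert idx.shape[0] == count
    return idx


def _n_relabelings(design: str, n_a: int, n_b: int) -> int:
    if design == "independent":
        n = n_a + n_b
        c = 1
        for i in range(1, n_a + 1):
            c = c * (n - n_a + i) // i
        return c
    return 2**n_a  # paired: sign pattern per pair


# ---------------------------------------------------------------------------
# t statistics (vectorized over shuffles x bins)


def _welch_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    """Unequal-variance two-sample t from per-group sums and sums of squares.

    Degenerate bins (zero variance in both groups) yield t = 0.  Consumes its
    array arguments (in-place arithmetic; shuffle matrices are large).
    """
    mean_a = sum_a
    mean_a /= n_a
    mean_b = sum_b
    mean_b /= n_b
    tmp = np.square(mean_a)
    tmp *= n_a
    var_a = sumsq_a
    var_a -= tmp
    np.maximum(var_a, 0.0, out=var_a)
    var_a /= (n_a - 1) * n_a  # directly var_a / n_a
    np.square(mean_b, out=tmp)
    tmp *= n_b
    var_b = sumsq_b
    var_b -= tmp
    np.maximum(var_b, 0.0, out=var_b)
    var_b /= (n_b - 1) * n_b
    denom = var_a
    denom += var_b
    np.sqrt(denom, out=denom)
    t = mean_a
    t -= mean_b
    ok = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t /= denom
    t[~ok] = 0.0
    return t, ok


def _paired_t(diff_sums, sumsq, n):
    """Paired t from the sum of (sign-flipped) differences.

    Sign flips leave each d_i^2 unchanged, so the sum of squares is shared by
    every relabeling.  Consumes ``diff_sums`` in place.
    """
    mean = diff_sums
    mean /= n
    var = np.square(mean)
    var *= n
    np.subtract(sumsq, var, out=var)
    np.maximum(var, 0.0, out=var)
    var /= (n - 1) * n
    denom = np.sqrt(var, out=var)
    ok = denom > 0
    t = mean
    with np.errstate(divide="ignore", invalid="ignore"):
        t /= denom
    t[~ok] = 0.0
    return t, ok


def _stack_maps(maps: list[TFTMap]) -> np.ndarray:
    if not maps:
        raise ValueError("need at least one map per group")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError("maps have heterogeneous dimensions")
    return np.stack([m.power for m in maps]), shape


# ---------------------------------------------------------------------------
# core engine


class _PermutationEngine:
    """Computes observed and shuffled t-maps plus per-bin permutation ranks.

    Shared by the bin-level and cluster-level tests so the shuffle set is
    generated once.
    """

    def __init__(self, maps_a, maps_b, design, n_shuffle, seed,
                 alpha_bin=DEFAULT_ALPHA_BIN, coi_mask=None):
        if design not in ("independent", "paired"):
            raise ValueError(f"design must be 'independent' or 'paired', got {design!r}")
        A, shape = _stack_maps(maps_a)
        B, shape_b = _stack_maps(maps_b)
        if shape != shape_b:
            raise ValueError("group maps have heterogeneous dimensions")
        self.shape = shape
        self.design = design
        self.n_a = A.shape[0]
        self.n_b = B.shape[0]
        if design == "paired" and self.n_a != self.n_b:
            raise ValueError("paired design needs equal-length map lists")
        min_n = 2
        if self.n_a < min_n or self.n_b < min_n:
            raise ValueError("need at least 2 maps per group")
        self.n_shuffle = int(n_shuffle)
        if self.n_shuffle < 1:
            raise ValueError("n_shuffle must be >= 1")
        self.seed = seed
        self.exclude_mask = None
        if coi_mask is not None:
            self.exclude_mask = np.asarray(coi_mask, dtype=bool).reshape(-1)

        nbins = shape[0] * shape[1]
        self._A = A.reshape(self.n_a, nbins)
        self._B = B.reshape(self.n_b, nbins)
        self.exact = _n_relabelings(design, self.n_a, self.n_b) <= self.n_shuffle
        self.alpha_bin = float(alpha_bin)
        min_p = 1.0 / _n_relabelings(design, self.n_a, self.n_b) if self.exact \
            else 1.0 / (self.n_shuffle + 1.0)
        if self.alpha_bin <= min_p:
            logger.warning(
                "alpha_bin=%g is unreachable: the smallest attainable "
                "permutation p is %g at %d relabelings; no bin can be marked "
                "significant — raise n_shuffle or alpha_bin",
                self.alpha_bin, min_p,
                self.n_shuffle if not self.exact
                else _n_relabelings(design, self.n_a, self.n_b))
        self._run()

    # -- shuffle construction ---------------------------------------------

    def _shuffled_t(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (t_obs, t_shuffles) with shapes (nbins,) and (S, nbins)."""
        rng = np.random.default_rng(self.seed)
        if self.design == "independent":
            X = np.concatenate([self._A, self._B], axis=0)  # (n, nbins)
            Xsq = X**2
            n, nbins = X.shape
            tot = X.sum(axis=0)
            totsq = Xsq.sum(axis=0)
            if self.exact:
                combos = _enumerate_independent(self.n_a, self.n_b)  # (N, n_a)
                S = combos.shape[0]
                sel = np.zeros((S, n), dtype=float)
                sel[np.arange(S)[:, None], combos] = 1.0
            else:
                S = self.n_shuffle
                sel = np.zeros((S, n), dtype=float)
                for s in range(S):
                    sel[s, rng.permutation(n)[: self.n_a]] = 1.0
            sum_a = sel @ X
            sumsq_a = sel @ Xsq
            t_sh, _ = _welch_t(sum_a, sumsq_a, self.n_a,
                               tot - sum_a, totsq - sumsq_a, self.n_b)
            t_obs, ok = _welch_t(X[: self.n_a].sum(axis=0),
                                 Xsq[: self.n_a].sum(axis=0), self.n_a,
                                 X[self.n_a:].sum(axis=0),
                                 Xsq[self.n_a:].sum(axis=0), self.n_b)
        else:  # paired
            D = self._A - self._B  # (n_pairs, nbins)
            n, nbins = D.shape
            sumsq = (D**2).sum(axis=0)
            if self.exact:
                S = 2**n
                signs = np.array(
                    [[1 if (s >> i) & 1 == 0 else -1 for i in range(n)]
                     for s in range(S)],
                    dtype=float,
                )
            else:
                S = self.n_shuffle
                signs = rng.choice([-1.0, 1.0], size=(S, n))
            t_sh, _ = _paired_t(signs @ D, sumsq, n)
            t_obs, ok = _paired_t(D.sum(axis=0), sumsq, n)
        self._degenerate = ~ok
        if np.any(self._degenerate):
            logger.info("%d degenerate bins (zero variance); p set to 1",
                        int(self._degenerate.sum()))
        return t_obs, t_sh

    # -- p-values from ranks ----------------------------------------------

    def _run(self) -> None:
        t_obs, t_sh = self._shuffled_t()
        abs_sh = np.abs(t_sh)
        abs_obs = np.abs(t_obs)
        if self.exact:
            # enumerated designs contain mathematically tied |t| values (e.g.
            # complementary assignments at equal group sizes) that differ in
            # the last ulp through summation order; quantize so such ties
            # count as ties
            abs_sh = abs_sh.astype(np.float32)
            abs_obs = abs_obs.astype(np.float32)
        S = abs_sh.shape[0]
        count_obs = (abs_sh >= abs_obs[None, :]).sum(axis=0)
        if self.exact:
            # exact p: proportion of relabelings (identity included) at least
            # as extreme; the identity is one of the enumerated relabelings
            p_obs = count_obs / S
            # shuffle s is significant iff #{|t*| >= |t_s|} < alpha * S,
            # i.e. count_ge (self included) <= K with K = ceil(alpha*S) - 1;
            # v passes iff strictly above the (K+1)-th largest in its bin
            K = int(np.ceil(self.alpha_bin * S - 1e-12)) - 1
            if K >= 1:
                kth = np.partition(abs_sh, S - K - 1, axis=0)[S - K - 1]
                sig_sh = abs_sh > kth[None, :]
            else:
                sig_sh = np.zeros_like(abs_sh, dtype=bool)
        else:
            p_obs = (1.0 + count_obs) / (1.0 + S)
            # the observed map joins the reference pool so that every map —
            # observed or shuffled — is thresholded by the same rank rule
            # over the same S+1 maps; under the null all S+1 are exchangeable
            # and the procedure's family-wise error is exact up to the
            # discreteness of the add-one estimator.  p < alpha means
            # #{shuffles >= me} <= K, i.e. rank <= K+1 (self included) in the
            # pool, i.e. strictly above the pool's (K+2)-th largest value.
            K = int(np.ceil(self.alpha_bin * (S + 1) - 1.0 - 1e-12)) - 1
            if K >= 0:
                pooled = np.vstack([abs_obs[None, :], abs_sh])
                kth = np.partition(pooled, S + 1 - K - 2, axis=0)[S + 1 - K - 2]
                sig_sh = abs_sh > kth[None, :]
            else:
                sig_sh = np.zeros_like(abs_sh, dtype=bool)
        p_obs = np.where(self._degenerate, 1.0, p_obs)
        sig_sh[:, self._degenerate] = False
        if self.exclude_mask is not None:
            p_obs = np.where(self.exclude_mask, 1.0, p_obs)
            sig_sh[:, self.exclude_mask] = False
        self.t_obs = t_obs.reshape(self.shape)
        self.p_obs = p_obs.reshape(self.shape)
        self._t_sh = t_sh
        self._sig_sh = sig_sh

    def bin_result(self) -> BinTestResult:
        return BinTestResult(
            t_map=self.t_obs,
            p_map=self.p_obs,
            sig_mask=self.p_obs < self.alpha_bin,
            alpha_bin=self.alpha_bin,
            n_shuffle=self.n_shuffle,
            exact=self.exact,
        )

    def null_max_masses(self, connectivity: int) -> np.ndarray:
        """Max |cluster mass| per shuffled map, thresholded like the observed."""
        S = self._t_sh.shape[0]
        out = np.zeros(S)
        for s in range(S):
            if not self._sig_sh[s].any():
                continue
            t_map = self._t_sh[s].reshape(self.shape)
            sig = self._sig_sh[s].reshape(self.shape)
            masses = _cluster_masses(t_map, sig, connectivity)
            if masses.size:
                out[s] = np.abs(masses).max()
        return out


# ---------------------------------------------------------------------------
# clustering


def _cluster_masses(t_map: np.ndarray, sig_mask: np.ndarray,
                    connectivity: int) -> np.ndarray:
    """Masses of sign-separated connected components (no bin bookkeeping)."""
    structure = _STRUCTURES[connectivity]
    masses = []
    for sign in (1, -1):
        mask = sig_mask & ((t_map > 0) if sign > 0 else (t_map < 0))
        labels, n = ndimage.label(mask, structure=structure)
        if n:
            masses.extend(ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1)))
    return np.asarray(masses)


def form_clusters(result: BinTestResult, connectivity: int = 4) -> list[Cluster]:
    """Join contiguous significant bins of like t-sign into clusters.

    ``connectivity`` 4 joins orthogonal neighbors on the trial x frequency
    grid; 8 also joins diagonals.  Positive- and negative-t clusters are
    formed separately.  Clusters are returned sorted by decreasing |mass|.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = _STRUCTURES[connectivity]
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = result.sig_mask & ((result.t_map > 0) if sign > 0
                                  else (result.t_map < 0))
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            bins = np.argwhere(labels == lab)
            mass = float(result.t_map[labels == lab].sum())
            clusters.append(Cluster(bins=bins, mass=mass, sign=sign))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


# ---------------------------------------------------------------------------
# model / results (primary user-facing surface)


class ClusterPermutationTest:
    """Two-group comparison of trial x frequency maps.

    Parameters
    ----------
    maps_a, maps_b
        Per-subject :class:`~trialwave.tft.TFTMap` lists.  For a paired
        design the lists must be index-aligned (subject i pre / subject i
        post).
    design
        ``"independent"`` (two groups of different subjects; unequal-variance
        two-sample t) or ``"paired"`` (same subjects twice; paired t with
        sign-flip relabeling).
    connectivity
        4 (orthogonal neighbors, default) or 8.
    include_coi
        If False, bins inside any subject's cone of influence are excluded
        from the test (their p is fixed at 1).

    Examples
    --------
    >>> test = ClusterPermutationTest(maps_ctrl, maps_pat)
    >>> res = test.fit(n_shuffle=5000, seed=42)
    >>> print(res.summary())
    """

    def __init__(self, maps_a: list[TFTMap], maps_b: list[TFTMap],
                 design: str = "independent", connectivity: int = 4,
                 include_coi: bool = True):
        if connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
        self.maps_a = list(maps_a)
        self.maps_b = list(maps_b)
        self.design = design
        self.connectivity = connectivity
        self.include_coi = include_coi

    def _coi_union(self):
        if self.include_coi:
            return None
        return np.logical_or.reduce(
            [m.coi_mask for m in self.maps_a + self.maps_b])

    def fit(self, n_shuffle: int = DEFAULT_N_SHUFFLE,
            alpha_bin: float = DEFAULT_ALPHA_BIN,
            alpha_cluster: float = DEFAULT_ALPHA_CLUSTER,
            seed: int | None = None) -> "ClusterPermutationResults":
        """Run both steps of the permutation procedure."""
        if not (0 < alpha_bin < 1 and 0 < alpha_cluster < 1):
            raise ValueError("alpha levels must lie in (0, 1)")
        engine = _PermutationEngine(self.maps_a, self.maps_b, self.design,
                                    n_shuffle, seed, alpha_bin=alpha_bin,
                                    coi_mask=self._coi_union())
        bin_result = engine.bin_result()
        clusters = form_clusters(bin_result, self.connectivity)
        null_max = engine.null_max_masses(self.connectivity)
        S = null_max.size
        for c in clusters:
            count = int(np.sum(null_max >= abs(c.mass)))
            if engine.exact:
                c.p_value = max(count, 1) / S
            else:
                c.p_value = (1.0 + count) / (1.0 + S)
        return ClusterPermutationResults(
            model=self,
            bin_result=bin_result,
            clusters=clusters,
            null_max_masses=null_max,
            alpha_cluster=alpha_cluster,
            n_shuffle=n_shuffle,
            seed=seed,
            exact=engine.exact,
        )


@dataclass
class ClusterPermutationResults:
    """Fitted comparison: clusters, their p-values, and bin-level maps."""

    model: ClusterPermutationTest
    bin_result: BinTestResult
    clusters: list[Cluster]
    null_max_masses: np.ndarray
    alpha_cluster: float
    n_shuffle: int
    seed: int | None
    exact: bool

    @property
    def t_map(self) -> np.ndarray:
        return self.bin_result.t_map

    @property
    def p_map(self) -> np.ndarray:
        return self.bin_result.p_map

    @property
    def sig_mask(self) -> np.ndarray:
        return self.bin_result.sig_mask

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha_cluster]

    @property
    def n_significant(self) -> int:
        return len(self.significant_clusters)

    @property
    def trials_covered_fraction(self) -> float:
        """Fraction of the T trials intersected by >=1 significant cluster."""
        T = self.t_map.shape[0]
        covered: set[int] = set()
        for c in self.significant_clusters:
            covered.update(int(t) for t in c.trials())
        return len(covered) / T

    def cluster_significance_mask(self) -> np.ndarray:
        """Boolean T x F mask of bins inside significant clusters."""
        mask = np.zeros(self.t_map.shape, dtype=bool)
        for c in self.significant_clusters:
            mask[c.bins[:, 0], c.bins[:, 1]] = True
        return mask

    def summary(self, max_rows: int = 12) -> str:
        """Human-readable table of the comparison (largest clusters first)."""
        T, F = self.t_map.shape
        lines = [
            "Cluster-based permutation comparison of trial x frequency maps",
            "=" * 66,
            f"design: {self.model.design}   "
            f"n_a={len(self.model.maps_a)}  n_b={len(self.model.maps_b)}   "
            f"map: {T} trials x {F} frequencies",
            f"n_shuffle={self.n_shuffle}"
            + (" (exhaustive enumeration)" if self.exact else "")
            + f"  alpha_bin={self.bin_result.alpha_bin}"
            f"  alpha_cluster={self.alpha_cluster}"
            f"  connectivity={self.model.connectivity}  seed={self.seed}",
            "-" * 66,
            f"significant clusters: {self.n_significant} of {len(self.clusters)}"
            f"   trials covered: {100 * self.trials_covered_fraction:.1f}%",
        ]
        if self.clusters:
            lines.append(
                f"{'#':>3} {'sign':>4} {'bins':>6} {'mass':>10} "
                f"{'trials':>11} {'freq idx':>10} {'p':>8}")
            for i, c in enumerate(self.clusters[:max_rows]):
                t0, t1 = c.trial_range
                f0, f1 = c.freq_range
                star = " *" if c.p_value < self.alpha_cluster else ""
                lines.append(
                    f"{i:>3} {('+' if c.sign > 0 else '-'):>4} {c.n_bins:>6} "
                    f"{c.mass:>10.2f} {f'{t0}-{t1}':>11} {f'{f0}-{f1}':>10} "
                    f"{c.p_value:>8.4f}{star}")
            if len(self.clusters) > max_rows:
                lines.append(f"... {len(self.clusters) - max_rows} smaller "
                             "clusters omitted")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "design": self.model.design,
            "n_a": len(self.model.maps_a),
            "n_b": len(self.model.maps_b),
            "n_shuffle": self.n_shuffle,
            "alpha_bin": self.bin_result.alpha_bin,
            "alpha_cluster": self.alpha_cluster,
            "connectivity": self.model.connectivity,
            "seed": self.seed,
            "exact": self.exact,
            "n_clusters": len(self.clusters),
            "n_significant": self.n_significant,
            "trials_covered_fraction": self.trials_covered_fraction,
            "clusters": [
                {
                    "sign": c.sign,
                    "n_bins": c.n_bins,
                    "mass": c.mass,
                    "p_value": c.p_value,
                    "significant": bool(c.p_value < self.alpha_cluster),
                    "trial_range": list(c.trial_range),
                    "freq_index_range": list(c.freq_range),
                }
                for c in self.clusters
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def significant_trial_intervals(self) -> list[tuple[int, int, int]]:
        """Per significant cluster, (cluster index, start, end) trial spans.

        Spans are 0-based half-open, BED-style.
        """
        out = []
        for i, c in enumerate(self.clusters):
            if c.p_value < self.alpha_cluster:
                t0, t1 = c.trial_range
                out.append((i, t0, t1 + 1))
        return out

    def plot(self, ax=None, show_boundaries: bool = True):
        """Plot the t-map with significant-cluster boundaries overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        T, F = self.t_map.shape
        vmax = max(np.abs(self.t_map).max(), 1e-12)
        im = ax.imshow(self.t_map.T, origin="lower", aspect="auto",
                       cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       extent=(0, T, 0, F))
        if show_boundaries and self.n_significant:
            ax.contour(np.arange(T) + 0.5, np.arange(F) + 0.5,
                       self.cluster_significance_mask().T.astype(float),
                       levels=[0.5], colors="white", linewidths=1.2)
        ax.set_xlabel("trial")
        ax.set_ylabel("frequency index")
        ax.figure.colorbar(im, ax=ax, label="t")
        return ax


# ---------------------------------------------------------------------------
# functional wrappers


def binwise_permutation_test(maps_a: list[TFTMap], maps_b: list[TFTMap],
                             design: str = "independent",
                             n_shuffle: int = DEFAULT_N_SHUFFLE,
                             alpha_bin: float = DEFAULT_ALPHA_BIN,
                             seed: int | None = None,
                             include_coi: bool = True) -> BinTestResult:
    """Step 1 only: per-bin t statistics and permutation p-values."""
    model = ClusterPermutationTest(maps_a, maps_b, design=design,
                                   include_coi=include_coi)
    engine = _PermutationEngine(maps_a, maps_b, design, n_shuffle, seed,
                                alpha_bin=alpha_bin,
                                coi_mask=model._coi_union())
    return engine.bin_result()


def cluster_permutation_test(maps_a: list[TFTMap], maps_b: list[TFTMap],
                             design: str = "independent",
                             n_shuffle: int = DEFAULT_N_SHUFFLE,
                             alpha_bin: float = DEFAULT_ALPHA_BIN,
                             alpha_cluster: float = DEFAULT_ALPHA_CLUSTER,
                             connectivity: int = 4,
                             seed: int | None = None,
                             include_coi: bool = True) -> ClusterPermutationResults:
    """Run the full two-step procedure (model + fit in one call)."""
    return ClusterPermutationTest(
        maps_a, maps_b, design=design, connectivity=connectivity,
        include_coi=include_coi,
    ).fit(n_shuffle=n_shuffle, alpha_bin=alpha_bin,
          alpha_cluster=alpha_cluster, seed=seed)


def report(result: ClusterPermutationResults) -> dict:
    """Structured summary: cluster count, extents, masses, p, coverage."""
    return {
        "n_clusters": len(result.clusters),
        "n_significant": result.n_significant,
        "trials_covered_fraction": result.trials_covered_fraction,
        "clusters": [
            {
                "sign": c.sign,
                "n_bins": c.n_bins,
                "mass": c.mass,
                "p_value": c.p_value,
                "trial_range": c.trial_range,
                "freq_index_range": c.freq_range,
            }
            for c in result.clusters
        ],
    }
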