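"""One-dimensional nonparametric statistical mapping over gait curves.

Node-wise repeated-measures statistics are computed across subjects at each
of the 101 (or 100) points of a stance-normalized curve, and family-wise
inference is obtained by permutation: condition labels are permuted within
subject (identically across all nodes of a subject, preserving curve-level
exchangeability), the maximum statistic over nodes is collected per
permutation, and the critical threshold is the empirical (1 - alpha)
quantile of that max distribution.  Contiguous supra-critical runs form
clusters; each observed cluster receives a p-value equal to the proportion
of permutations whose largest supra-critical cluster extent is at least as
large.

The omnibus test is a one-way repeated-measures ANOVA F map (subject as
block); post hoc paired contrasts use node-wise paired t maps with a
within-subject sign-flip null and Bonferroni-adjusted alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from ._rng import substream

__all__ = [
    "CurveSample",
    "SnPMResult",
    "Cluster",
    "shapiro_wilk",
    "snpm_rm_anova",
    "snpm_paired_posthoc",
    "STRIDE_PHASE_BANDS",
]

#: Stride-phase annotation bands (percent of normalized stance) used only
#: for labeling outputs: initial contact, foot flat, swing, end of swing.
STRIDE_PHASE_BANDS: dict[str, tuple[float, float]] = {
    "initial_contact": (0.0, 10.0),
    "foot_flat": (11.0, 25.0),
    "swing": (26.0, 75.0),
    "end_of_swing": (76.0, 100.0),
}


@dataclass(frozen=True)
class CurveSample:
    """One subject's curve under one condition."""

    subject_id: int
    direction: int
    curve: np.ndarray


@dataclass(frozen=True)
class Cluster:
    """A supra-critical run: half-open node interval plus stride percents."""

    start: int
    end: int  # exclusive
    start_pct: float
    end_pct: float
    p_value: float

    @property
    def extent(self) -> int:
        return self.end - self.start


@dataclass
class SnPMResult:
    stat_curve: np.ndarray
    critical: float
    clusters: list[Cluster]
    alpha: float
    n_perm: int
    exhaustive: bool = False
    zero_variance_nodes: np.ndarray | None = None
    stat_name: str = "F"

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a 1-D sample (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or not 3 <= values.size <= 5000:
        raise ValueError("shapiro_wilk needs a 1-D sample with 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("constant sample: the W statistic is undefined")
    res = spstats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


# --- helpers --------------------------------------------------------------

def _stack(samples: list[CurveSample]) -> tuple[np.ndarray, list[int], list[int]]:
    """Arrange samples as Y[subject, condition, node]; every subject must be
    complete."""
    subjects = sorted({s.subject_id for s in samples})
    directions = sorted({s.direction for s in samples})
    if len(directions) < 2:
        raise ValueError("need at least two conditions")
    lookup = {(s.subject_id, s.direction): np.asarray(s.curve, float)
              for s in samples}
    if len(lookup) != len(samples):
        raise ValueError("duplicate (subject, condition) curve")
    n_nodes = len(next(iter(lookup.values())))
    Y = np.empty((len(subjects), len(directions), n_nodes))
    for i, subj in enumerate(subjects):
        for j, cond in enumerate(directions):
            if (subj, cond) not in lookup:
                raise ValueError(
                    f"subject {subj} has no curve for condition {cond}"
                )
            curve = lookup[(subj, cond)]
            if len(curve) != n_nodes:
                raise ValueError(f"subject {subj} curve length mismatch")
            Y[i, j] = curve
    return Y, subjects, directions


def _max_cluster_extents(above: np.ndarray) -> np.ndarray:
    """Per row of a boolean (M, Q) array, the longest run of True (0 if none)."""
    M, Q = above.shape
    padded = np.zeros((M, Q + 2), dtype=np.int8)
    padded[:, 1:-1] = above
    d = np.diff(padded, axis=1)
    out = np.zeros(M, dtype=int)
    rows, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)
    lengths = ends - starts
    np.maximum.at(out, rows, lengths)
    return out


def _clusters_from_stat(stat: np.ndarray, critical: float,
                        null_extents: np.ndarray, n_perm: int) -> list[Cluster]:
    above = stat > critical
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    n_nodes = len(stat)
    clusters = []
    for s, e in zip(starts, ends):
        extent = e - s
        p = float(np.mean(null_extents >= extent))
        p = max(p, 1.0 / n_perm)
        # node index -> stride percent on a 0..100% axis
        scale = 100.0 / (n_nodes - 1)
        clusters.append(
            Cluster(start=int(s), end=int(e), start_pct=float(s * scale),
                    end_pct=float((e - 1) * scale), p_value=p)
        )
    return clusters


def _rm_anova_f(Y: np.ndarray) -> np.ndarray:
    """Node-wise one-way repeated-measures F for Y[subject, cond, node]."""
    n, k, _ = Y.shape
    grand = Y.mean(axis=(0, 1))
    cond_mean = Y.mean(axis=0)  # (k, Q)
    subj_mean = Y.mean(axis=1)  # (n, Q)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=0)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_tot = ((Y - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_cond / df_cond) / (ss_err / df_err)
    return np.where(np.isfinite(F), F, 0.0)


def snpm_rm_anova(samples: list[CurveSample], n_perm: int = 10_000,
                  alpha: float = 0.05, seed: int = 0) -> SnPMResult:
    """Permutation repeated-measures one-way ANOVA over curves.

    The null is built by permuting condition labels within subject,
    identically across all nodes of that subject.  The identity labeling is
    always included as the first permutation.  When the exhaustive label
    permutation count (k!)^n does not exceed ``n_perm``, all labelings are
    enumerated and the result no longer depends on the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y, subjects, directions = _stack(samples)
    n, k, Q = Y.shape
    F_obs = _rm_anova_f(Y)

    n_exhaustive = math.factorial(k) ** n
    exhaustive = n_exhaustive <= n_perm
    perms = _condition_permutations(n, k, n_perm, exhaustive, seed)
    M = perms.shape[0]

    # Subject and total sums of squares are invariant under within-subject
    # label permutation, so only the condition means need recomputation.
    grand = Y.mean(axis=(0, 1))
    ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum(axis=0)
    ss_tot = ((Y - grand) ** 2).sum(axis=(0, 1))
    resid_base = ss_tot - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)

    max_f = np.empty(M)
    F_perm_rows: list[np.ndarray] = []
    chunk = max(1, int(2e7 // (n * k * Q)))
    subj_idx = np.arange(n)[None, :, None]
    for lo in range(0, M, chunk):
        p = perms[lo:lo + chunk]  # (c, n, k)
        Yp = Y[subj_idx, p, :]  # (c, n, k, Q)
        cond_mean = Yp.mean(axis=1)  # (c, k, Q)
        ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=1)  # (c, Q)
        with np.errstate(invalid="ignore", divide="ignore"):
            Fp = (ss_cond / df_cond) / ((resid_base - ss_cond) / df_err)
        Fp = np.where(np.isfinite(Fp), Fp, 0.0)
        max_f[lo:lo + len(p)] = Fp.max(axis=1)
        F_perm_rows.append(Fp)
    F_perm = np.vstack(F_perm_rows)

    critical = float(np.quantile(max_f, 1.0 - alpha, method="higher"))
    null_extents = _max_cluster_extents(F_perm > critical)
    clusters = _clusters_from_stat(F_obs, critical, null_extents, M)
    return SnPMResult(stat_curve=F_obs, critical=critical, clusters=clusters,
                      alpha=alpha, n_perm=M, exhaustive=exhaustive,
                      stat_name="F")


def _condition_permutations(n: int, k: int, n_perm: int, exhaustive: bool,
                            seed: int) -> np.ndarray:
    """(M, n, k) arrays of within-subject condition index assignments."""
    base = np.arange(k)
    if exhaustive:
        per_subject = [np.array(p) for p in itertools.permutations(range(k))]
        combos = itertools.product(range(len(per_subject)), repeat=n)
        perms = np.array(
            [[per_subject[c] for c in combo] for combo in combos], dtype=int
        )
        # ensure identity first
        ident = np.tile(base, (n, 1))
        first = np.nonzero((perms == ident).all(axis=(1, 2)))[0][0]
        perms[[0, first]] = perms[[first, 0]]
        return perms
    rng = substream(seed, "snpm-rm-anova")
    perms = np.empty((n_perm, n, k), dtype=int)
    perms[0] = np.tile(base, (n, 1))
    for i in range(1, n_perm):
        perms[i] = rng.permuted(np.tile(base, (n, 1)), axis=1)
    return perms


def snpm_paired_posthoc(samples: list[CurveSample],
                        pair: tuple[int, int], n_perm: int = 10_000,
                        alpha_adjusted: float = 0.05 / 3,
                        seed: int = 0) -> SnPMResult:
    """Node-wise paired t map with a within-subject sign-flip null.

    ``alpha_adjusted`` should already carry the Bonferroni correction
    (alpha / number of pairwise comparisons).  With n subjects the
    exhaustive null has 2**n sign patterns and is enumerated whenever
    ``n_perm`` is at least that large; the two-sided statistic is |t|.
    Nodes where the difference curve has zero variance get t = 0 and are
    reported in ``zero_variance_nodes``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a, b = pair
    wanted = [s for s in samples if s.direction in (a, b)]
    Y, subjects, directions = _stack(wanted)
    ia, ib = directions.index(a), directions.index(b)
    D = Y[:, ia, :] - Y[:, ib, :]  # (n, Q)
    n, Q = D.shape

    exhaustive = 2**n <= n_perm
    if exhaustive:
        M = 2**n
        bits = (np.arange(M)[:, None] >> np.arange(n)[None, :]) & 1
        signs = 1 - 2 * bits.astype(float)  # row 0 = all +1 (identity)
    else:
        rng = substream(seed, "snpm-paired", a, b)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        signs[0] = 1.0
        M = n_perm

    sumsq = (D**2).mean(axis=0)  # invariant under sign flips
    mean_p = signs @ D / n  # (M, Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_p = (sumsq[None, :] - mean_p**2) * n / (n - 1)
        t_p = mean_p / np.sqrt(var_p / n)
    zero_var = ~np.isfinite(t_p[0])
    t_p = np.where(np.isfinite(t_p), t_p, 0.0)
    t_abs = np.abs(t_p)

    max_t = t_abs.max(axis=1)
    critical = float(np.quantile(max_t, 1.0 - alpha_adjusted, method="higher"))
    null_extents = _max_cluster_extents(t_abs > critical)
    clusters = _clusters_from_stat(t_abs[0], critical, null_extents, M)
    return SnPMResult(stat_curve=t_p[0], critical=critical, clusters=clusters,
                      alpha=alpha_adjusted, n_perm=M, exhaustive=exhaustive,
                      zero_variance_nodes=zero_var, stat_name="t")
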