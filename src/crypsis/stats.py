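"""Two-step discriminability statistics on JND distance matrices.

The question "does the animal's colour differ from the background for this
receiver?" is answered in two steps. Step one asks whether the two clouds of
colour samples are *statistically* separate: a PERMANOVA (permutational
MANOVA on the pairwise JND distance matrix, Anderson's pseudo-F), preceded
by a multivariate dispersion (Levene-type) test of its homogeneity
assumption. Step two asks whether the separation is *perceptually*
meaningful: the chromatic distance between group centroids (geometric means
of quantum catches) with a bootstrap 95% confidence interval, judged against
the 1-JND discrimination threshold and a 3-JND "may still be
indistinguishable" band.

The combined decision rule: the animal is considered camouflaged (matches
the background) when the PERMANOVA is not significant, or when the CI
crosses 1 JND and the mean distance is below 3 JND; it is discriminable when
the PERMANOVA is significant and the CI sits entirely above 1 JND.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .receptor import (
    JND_INDISTINGUISHABLE,
    JND_POSSIBLY_INDISTINGUISHABLE,
    NoiseModel,
    QuantumCatchVector,
    rnl_distance,
)

#: Exhaustive permutation enumeration is used when the number of distinct
#: group assignments does not exceed this.
EXHAUSTIVE_LIMIT = 10_000


@dataclass
class JndDistanceMatrix:
    """Symmetric matrix of pairwise chromatic distances (JND) with group tags."""

    labels: list[str]
    groups: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n) or len(self.groups) != n:
            raise ValueError("labels, groups and matrix dimensions disagree")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def group_indices(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        g = np.asarray(self.groups)
        for name in dict.fromkeys(self.groups):  # preserve first-seen order
            out[name] = np.flatnonzero(g == name)
        return out


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_permutations: int
    df: tuple[int, int]
    method: str = "monte-carlo"

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"p-value {self.p} outside (0, 1]")


@dataclass
class DispersionResult:
    statistic: float
    p: float
    smaller_group_more_variable: bool
    group_dispersions: dict[str, float]


@dataclass
class BootstrapContrast:
    """Geometric-mean centroid distance between two groups with bootstrap CI."""

    mean_jnd: float
    ci_low: float
    ci_high: float
    n_boot: int

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.ci_high):
            raise ValueError("require 0 <= ci_low <= ci_high")
        if self.mean_jnd < 0:
            raise ValueError("mean JND must be non-negative")


@dataclass
class MatchDecision:
    verdict: str  # camouflaged | discriminable | ambiguous
    rule_fired: str


def jnd_distance_matrix(
    samples: Sequence[QuantumCatchVector],
    noise: NoiseModel,
    signal_form: str = "log",
) -> JndDistanceMatrix:
    """All pairwise RNL distances between colour samples, preserving group tags."""
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = rnl_distance(samples[i], samples[j], noise, signal_form)
    return JndDistanceMatrix(
        labels=[s.stimulus_label for s in samples],
        groups=[s.group for s in samples],
        d=d,
    )


def _two_group_indices(dm: JndDistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    gi = dm.group_indices()
    if len(gi) != 2:
        raise ValueError(f"exactly 2 groups required, found {list(gi)}")
    a, b = gi.values()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    return a, b


def _pseudo_f_batch(d2: np.ndarray, member_a: np.ndarray, n_a: int) -> np.ndarray:
    """Anderson's pseudo-F for many group-A membership vectors at once.

    ``member_a`` is a (n_assignments, n) 0/1 matrix. SS_total and SS_within
    are computed from squared distances; F = (SS_t - SS_w) / (SS_w / (n-2)).
    """
    n = d2.shape[0]
    n_b = n - n_a
    ss_total = d2.sum() / (2.0 * n)
    within_a = np.einsum("pi,ij,pj->p", member_a, d2, member_a) / 2.0
    member_b = 1.0 - member_a
    within_b = np.einsum("pi,ij,pj->p", member_b, d2, member_b) / 2.0
    ss_within = within_a / n_a + within_b / n_b
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / (ss_within / (n - 2))
    # degenerate: no within-group variation at all
    f = np.where(ss_within <= 0, np.where(ss_between > 0, np.inf, 0.0), f)
    return f


def permanova(
    dm: JndDistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool | None = None,
) -> PermanovaResult:
    """Two-group PERMANOVA on a distance matrix.

    The p-value is (1 + #{permuted F >= observed F}) / (1 + n_perm) for
    Monte-Carlo label permutations, or the exact proportion over all
    distinct assignments when these number at most ``EXHAUSTIVE_LIMIT``
    (or when ``exhaustive=True``).
    """
    idx_a, idx_b = _two_group_indices(dm)
    n = dm.n
    n_a = len(idx_a)
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives a very coarse p-value; use >= 99", stacklevel=2)
    d2 = dm.d**2

    obs_member = np.zeros((1, n))
    obs_member[0, idx_a] = 1.0
    f_obs = float(_pseudo_f_batch(d2, obs_member, n_a)[0])

    n_assignments = math.comb(n, n_a)
    if exhaustive is None:
        exhaustive = n_assignments <= EXHAUSTIVE_LIMIT
    if exhaustive:
        member = np.zeros((n_assignments, n))
        for row, combo in enumerate(combinations(range(n), n_a)):
            member[row, list(combo)] = 1.0
        f_all = _pseudo_f_batch(d2, member, n_a)
        p = float(np.mean(f_all >= f_obs - 1e-12))
        return PermanovaResult(f_obs, p, n_assignments, (1, n - 2), method="exhaustive")

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    member = np.zeros((n_perm, n))
    rows = np.repeat(np.arange(n_perm), n_a)
    member[rows, order[:, :n_a].ravel()] = 1.0
    f_perm = _pseudo_f_batch(d2, member, n_a)
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_perm)
    return PermanovaResult(f_obs, float(p), n_perm, (1, n - 2), method="monte-carlo")


def _pcoa_distances_to_centroids(dm: JndDistanceMatrix) -> np.ndarray:
    """Per-sample distance to its own group's spatial centroid.

    Principal-coordinate embedding of the distance matrix; axes with
    negative eigenvalues contribute negatively to squared distances
    (Anderson's correction), clipped at zero.
    """
    n = dm.n
    d2 = dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    tol = 1e-10 * max(1.0, np.abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    coords_pos = vecs[:, pos] * np.sqrt(vals[pos])
    coords_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    z2 = np.zeros(n)
    for idx in dm.group_indices().values():
        cp = coords_pos[idx].mean(axis=0) if coords_pos.size else np.zeros(0)
        cn = coords_neg[idx].mean(axis=0) if coords_neg.size else np.zeros(0)
        dp2 = ((coords_pos[idx] - cp) ** 2).sum(axis=1) if coords_pos.size else 0.0
        dn2 = ((coords_neg[idx] - cn) ** 2).sum(axis=1) if coords_neg.size else 0.0
        z2[idx] = np.clip(dp2 - dn2, 0.0, None)
    return np.sqrt(z2)


def dispersion_test(
    dm: JndDistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> DispersionResult:
    """Multivariate Levene-type test of homogeneity of group dispersions.

    ANOVA F on per-sample distances to own-group centroids in
    principal-coordinate space, with a label-permutation p-value. The result
    flags the PERMANOVA type-I-error caveat: the smaller group being more
    dispersed than the larger one.
    """
    idx_a, idx_b = _two_group_indices(dm)
    z = _pcoa_distances_to_centroids(dm)
    gi = dm.group_indices()
    names = list(gi)
    disp = {name: float(z[idx].mean()) for name, idx in gi.items()}

    sizes = {name: len(idx) for name, idx in gi.items()}
    smaller = min(names, key=lambda k: sizes[k])
    larger = max(names, key=lambda k: sizes[k])
    flag = sizes[smaller] < sizes[larger] and disp[smaller] > disp[larger]

    if np.allclose(z, 0.0):
        return DispersionResult(0.0, 1.0, False, disp)

    def anova_f(values: np.ndarray) -> float:
        za, zb = values[idx_a], values[idx_b]
        grand = values.mean()
        ss_b = len(za) * (za.mean() - grand) ** 2 + len(zb) * (zb.mean() - grand) ** 2
        ss_w = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
        if ss_w <= 0:
            return np.inf if ss_b > 0 else 0.0
        return float(ss_b / (ss_w / (len(values) - 2)))

    f_obs = anova_f(z)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += anova_f(rng.permutation(z)) >= f_obs - 1e-12
    p = (1.0 + count) / (1.0 + n_perm)
    return DispersionResult(f_obs, float(p), bool(flag), disp)


def _geometric_centroid_log(catches: np.ndarray) -> np.ndarray:
    """Log of the per-receptor geometric mean of a (n_samples, n_receptors) array."""
    if np.any(catches <= 0):
        raise ValueError("geometric-mean centroids require strictly positive catches")
    return np.log(catches).mean(axis=0)


def _rnl_from_df(df: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Trichromat RNL distance from log catch-ratio differences (vectorised)."""
    e1, e2, e3 = e
    f1, f2, f3 = df[..., 0], df[..., 1], df[..., 2]
    num = (e1 * (f3 - f2)) ** 2 + (e2 * (f3 - f1)) ** 2 + (e3 * (f1 - f2)) ** 2
    den = (e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2
    return np.sqrt(num / den)


def bootstrap_centroid_jnd(
    group_a: Sequence[QuantumCatchVector],
    group_b: Sequence[QuantumCatchVector],
    noise: NoiseModel,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> BootstrapContrast:
    """Chromatic distance between group centroids with a bootstrap 95% CI.

    Each group's centroid is the per-receptor geometric mean of quantum
    catches; the statistic is the RNL distance between centroids. Groups are
    resampled with replacement ``n_boot`` times and the CI is the 2.5/97.5
    percentile of the bootstrap distribution.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples to bootstrap")
    qa = np.array([g.values for g in group_a])
    qb = np.array([g.values for g in group_b])
    la = _geometric_centroid_log(qa)
    lb = _geometric_centroid_log(qb)
    point = float(_rnl_from_df((la - lb)[None, :], noise.e)[0])

    rng = np.random.default_rng(seed)
    log_a = np.log(qa)
    log_b = np.log(qb)
    ia = rng.integers(len(group_a), size=(n_boot, len(group_a)))
    ib = rng.integers(len(group_b), size=(n_boot, len(group_b)))
    cent_a = log_a[ia].mean(axis=1)
    cent_b = log_b[ib].mean(axis=1)
    dist = _rnl_from_df(cent_a - cent_b, noise.e)
    lo, hi = np.percentile(dist, [2.5, 97.5])
    # the percentile CI is built around the bootstrap distribution; keep the
    # point estimate inside the reported interval
    lo = min(float(lo), point)
    hi = max(float(hi), point)
    return BootstrapContrast(mean_jnd=point, ci_low=lo, ci_high=hi, n_boot=n_boot)


def discriminability_decision(
    perm: PermanovaResult,
    boot: BootstrapContrast,
    alpha: float = 0.05,
    jnd_threshold: float = JND_INDISTINGUISHABLE,
    jnd_upper: float = JND_POSSIBLY_INDISTINGUISHABLE,
) -> MatchDecision:
    """Combine the statistical and perceptual steps into a verdict.

    camouflaged:   PERMANOVA not significant; or CI crosses the 1-JND
                   threshold with mean JND below 3.
    discriminable: PERMANOVA significant and CI entirely above 1 JND.
    ambiguous:     significant, CI crosses 1 JND, but mean JND >= 3 —
                   outside the published rule, surfaced explicitly.
    """
    if perm.p >= alpha:
        return MatchDecision("camouflaged", f"PERMANOVA p={perm.p:.4g} >= alpha={alpha}")
    if boot.ci_low > jnd_threshold:
        return MatchDecision(
            "discriminable",
            f"PERMANOVA p={perm.p:.4g} < alpha and CI low {boot.ci_low:.3g} > {jnd_threshold} JND",
        )
    if boot.mean_jnd < jnd_upper:
        return MatchDecision(
            "camouflaged",
            f"CI crosses {jnd_threshold} JND and mean {boot.mean_jnd:.3g} < {jnd_upper} JND",
        )
    return MatchDecision(
        "ambiguous",
        f"significant, CI crosses {jnd_threshold} JND, but mean {boot.mean_jnd:.3g} >= {jnd_upper} JND",
    )
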