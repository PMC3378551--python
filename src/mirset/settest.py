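"""One-sided gene-set tests producing directional p-values per target set.

Every test reports (p_set_up, p_set_down) for one miRNA's target set:
the evidence that the set's mRNAs are up- (respectively down-) regulated
in group 2.  Competitive tests (KS, Wilcoxon, Fisher's exact, the
rotation-based mean-rank test) judge the set against the rest of the
measured genes; self-contained tests (rotation mean-statistic test,
global quadratic-form test) look at the set's genes only.

A registry maps test names to implementations so external gene-set tests
can be plugged in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg, special, stats

from .core import ExpressionMatrix, GroupDesign, ValidationError
from .feature import FeatureStats, estimate_prior, fit_two_group_model

logger = logging.getLogger("mirset")

DEFAULT_N_ROT = 1000
DEFAULT_N_PERM = 1000
DEFAULT_TAU = 0.05


@dataclass
class SetTestResult:
    """Directional p-values for one (miRNA, target set) pair."""

    mirna_id: str
    test_name: str
    p_set_up: float
    p_set_down: float
    set_size: int
    complementary: bool  # does p_set_up + p_set_down = 1 hold for this family?


@dataclass
class RankData:
    """Per-direction ranks over all measured mRNAs (rank 1 = most significant)."""

    feature_ids: list[str]
    rank_up: np.ndarray
    rank_down: np.ndarray

    _index: dict[str, int] | None = None

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    def member_indices(self, members) -> np.ndarray:
        if self._index is None:
            self._index = {f: i for i, f in enumerate(self.feature_ids)}
        idx = self._index
        return np.asarray(sorted(idx[m] for m in members if m in idx), dtype=int)


def rank_by_direction(mrna_stats: FeatureStats) -> RankData:
    """Assign, per direction, rank 1..p by ascending one-sided p-value.

    Ties are broken deterministically by feature id.
    """
    ids = np.asarray(mrna_stats.feature_ids)
    id_order = np.argsort(ids, kind="stable")

    def ranks_for(p_vals: np.ndarray) -> np.ndarray:
        order = id_order[np.argsort(p_vals[id_order], kind="stable")]
        r = np.empty(len(ids), dtype=float)
        r[order] = np.arange(1, len(ids) + 1)
        return r

    return RankData(
        feature_ids=list(mrna_stats.feature_ids),
        rank_up=ranks_for(mrna_stats.p_up),
        rank_down=ranks_for(mrna_stats.p_down),
    )


# ---------------------------------------------------------------------------
# Competitive rank / enrichment tests
# ---------------------------------------------------------------------------

def ks_one_sided(member_ranks: np.ndarray, p: int) -> float:
    """One-sided one-sample KS p toward low ranks.

    D+ = max_i (i/m - u_(i)) with u the sorted normalized member ranks;
    p-value from the asymptotic bound exp(-2 m D+^2), clipped to [0, 1].
    """
    m = len(member_ranks)
    if m == 0:
        raise ValidationError("empty set")
    u = np.sort(member_ranks) / p
    d_plus = np.max(np.arange(1, m + 1) / m - u)
    d_plus = max(d_plus, 0.0)
    return float(min(1.0, math.exp(-2.0 * m * d_plus**2)))


def ks_set_test(ctx: "SetTestContext", members, mirna_id: str) -> SetTestResult:
    ranks = ctx.ranks()
    idx = ranks.member_indices(members)
    if idx.size == 0:
        raise ValidationError(f"empty set for miRNA {mirna_id!r}")
    return SetTestResult(
        mirna_id=mirna_id,
        test_name="ks",
        p_set_up=ks_one_sided(ranks.rank_up[idx], ranks.p),
        p_set_down=ks_one_sided(ranks.rank_down[idx], ranks.p),
        set_size=idx.size,
        complementary=False,
    )


def wilcoxon_one_sided(member_ranks: np.ndarray, p: int) -> float:
    """Normal-approximation rank-sum p for enrichment toward low ranks.

    No continuity correction, so the p-values for a ranking and its
    reverse sum exactly to one.
    """
    m = len(member_ranks)
    if m == 0:
        raise ValidationError("empty set")
    if m >= p:
        raise ValidationError("set equals the whole universe: no outside genes")
    w = float(np.sum(member_ranks))
    mean_w = m * (p + 1) / 2.0
    sd_w = math.sqrt(m * (p - m) * (p + 1) / 12.0)
    z = (w - mean_w) / sd_w
    return float(stats.norm.cdf(z))


def wilcoxon_set_test(ctx: "SetTestContext", members, mirna_id: str) -> SetTestResult:
    ranks = ctx.ranks()
    idx = ranks.member_indices(members)
    return SetTestResult(
        mirna_id=mirna_id,
        test_name="wilcoxon",
        p_set_up=wilcoxon_one_sided(ranks.rank_up[idx], ranks.p),
        p_set_down=wilcoxon_one_sided(ranks.rank_down[idx], ranks.p),
        set_size=idx.size,
        complementary=True,
    )


def fisher_exact_enrichment(calls: np.ndarray, in_set: np.ndarray) -> float:
    """Upper-tail hypergeometric p for DE over-representation in the set."""
    p = len(calls)
    big_k = int(calls.sum())
    m = int(in_set.sum())
    k = int((calls & in_set).sum())
    if m == 0:
        raise ValidationError("empty set")
    # sf(k-1) is the P(X >= k) upper tail; equals 1 when no DE calls exist
    return float(min(1.0, stats.hypergeom.sf(k - 1, p, big_k, m)))


def fisher_exact_set_test(ctx: "SetTestContext", members, mirna_id: str) -> SetTestResult:
    st = ctx.mrna_stats
    idx = ctx.ranks().member_indices(members)
    if idx.size == 0:
        raise ValidationError(f"empty set for miRNA {mirna_id!r}")
    in_set = np.zeros(len(st.feature_ids), dtype=bool)
    in_set[idx] = True
    tau = ctx.tau
    return SetTestResult(
        mirna_id=mirna_id,
        test_name="fisher_exact",
        p_set_up=fisher_exact_enrichment(st.p_up <= tau, in_set),
        p_set_down=fisher_exact_enrichment(st.p_down <= tau, in_set),
        set_size=int(in_set.sum()),
        complementary=False,
    )


# ---------------------------------------------------------------------------
# Self-contained quadratic-form (global) test
# ---------------------------------------------------------------------------

def split_set_by_direction(
    mrna: ExpressionMatrix, design: GroupDesign, members
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition a gene set by observed direction of regulation.

    A gene goes to the "up" subset when its group-2 mean exceeds its
    group-1 mean, to "down" when smaller; exact ties join neither side.
    """
    ind = design.indicator(mrna.sample_ids) == 1
    idx = {f: i for i, f in enumerate(mrna.feature_ids)}
    up, down, tied = set(), set(), 0
    for g in members:
        if g not in idx:
            continue
        row = mrna.values[idx[g]]
        m2, m1 = row[ind].mean(), row[~ind].mean()
        if m2 > m1:
            up.add(g)
        elif m2 < m1:
            down.add(g)
        else:
            tied += 1
    if tied:
        logger.info("split_set_by_direction: %d genes with exactly equal means excluded", tied)
    return frozenset(up), frozenset(down)


def global_q_statistic(x_centered: np.ndarray, y: np.ndarray) -> float:
    """Q = (y - ybar)' X X' (y - ybar) for column-centered X (samples x genes)."""
    resid = y - y.mean()
    return float(np.sum((x_centered.T @ resid) ** 2))


def global_q_test_subset(
    mrna: ExpressionMatrix,
    design: GroupDesign,
    subset,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value of the quadratic-form association statistic for
    one gene subset; returns 1 (with a warning) when the subset is empty."""
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    idx = {f: i for i, f in enumerate(mrna.feature_ids)}
    rows = sorted(idx[g] for g in subset if g in idx)
    if not rows:
        logger.warning("global_q_test: empty subset, returning p = 1")
        return 1.0
    x = mrna.values[rows].T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    y = design.indicator(mrna.sample_ids)
    q_obs = global_q_statistic(x, y)
    resid = y - y.mean()
    perms = np.stack([rng.permutation(resid) for _ in range(n_perm)], axis=1)
    q_perm = np.sum((x.T @ perms) ** 2, axis=0)
    b = int(np.sum(q_perm >= q_obs))
    return (1 + b) / (n_perm + 1)


def global_q_set_test(ctx: "SetTestContext", members, mirna_id: str) -> SetTestResult:
    """Directional global-test p-values via direction-split subsets."""
    up_sub, down_sub = split_set_by_direction(ctx.mrna, ctx.design, members)
    p_up = global_q_test_subset(ctx.mrna, ctx.design, up_sub, ctx.n_perm, ctx.rng)
    p_down = global_q_test_subset(ctx.mrna, ctx.design, down_sub, ctx.n_perm, ctx.rng)
    return SetTestResult(
        mirna_id=mirna_id,
        test_name="globalq",
        p_set_up=p_up,
        p_set_down=p_down,
        set_size=len(up_sub) + len(down_sub),
        complementary=False,
    )


# ---------------------------------------------------------------------------
# Rotation tests
# ---------------------------------------------------------------------------

class RotationContext:
    """Reduced effect + residual representation of an expression matrix.

    Each gene's sample vector is projected onto an orthonormal basis whose
    first coordinate carries the two-group contrast (positive = higher in
    group 2) and whose remaining d = n - 2 coordinates span the residual
    space.  A rotation draws one random unit (d+1)-vector shared by all
    genes, which preserves inter-gene correlation, and recomputes every
    gene's moderated t (with the prior held fixed at its observed
    estimate) and normal score z.
    """

    def __init__(self, mrna: ExpressionMatrix, design: GroupDesign):
        ind = design.indicator(mrna.sample_ids)
        n = len(ind)
        g2 = ind == 1
        n1, n2 = int((~g2).sum()), int(g2.sum())
        if n1 < 2 or n2 < 2:
            raise ValidationError("rotation tests need >=2 samples per group")
        contrast = np.where(g2, 1.0 / n2, -1.0 / n1)
        q2 = contrast / np.linalg.norm(contrast)
        q1 = np.full(n, 1.0 / math.sqrt(n))
        u = linalg.null_space(np.stack([q1, q2]))  # n x (n-2), orthonormal
        self.d = n - 2
        y = mrna.values
        effect = y @ q2                       # genes
        residuals = y @ u                     # genes x d
        self.vectors = np.column_stack([effect, residuals])  # genes x (d+1)
        self.feature_ids = list(mrna.feature_ids)
        s_sq = (residuals**2).sum(axis=1) / self.d
        hyper = estimate_prior(s_sq, self.d)
        self.d0, self.s0_sq = hyper.d0, hyper.s0_sq
        self.df_total = math.inf if math.isinf(self.d0) else self.d0 + self.d
        self._t_cache: dict[tuple[int, int], np.ndarray] = {}
        self._z_cache: dict[tuple[int, int], np.ndarray] = {}
        self._rank_cache: dict[tuple[int, int], np.ndarray] = {}

    def _t_scores(self, effect: np.ndarray, total_sq: np.ndarray) -> np.ndarray:
        """Moderated t statistic recomputed from a (rotated) effect."""
        d = self.d
        resid_sq = np.maximum(total_sq - effect**2, 0.0)
        s_sq = resid_sq / d
        if math.isinf(self.d0):
            s_tilde = np.full_like(s_sq, self.s0_sq)
        else:
            s_tilde = (self.d0 * self.s0_sq + d * s_sq) / (self.d0 + d)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / np.sqrt(s_tilde)
        return np.asarray(np.where(s_tilde == 0, np.sign(effect) * np.inf, t), dtype=float)

    def _t_to_z(self, t: np.ndarray) -> np.ndarray:
        """Map a moderated t to a standard normal score (rank-preserving)."""
        if math.isinf(self.df_total):
            return t
        cdf = special.stdtr(self.df_total, t)
        cdf = np.clip(cdf, 1e-300, 1 - 1e-16)
        return special.ndtri(cdf)

    def observed_t(self) -> np.ndarray:
        v = self.vectors
        return self._t_scores(v[:, 0], (v**2).sum(axis=1))

    def observed_z(self) -> np.ndarray:
        return self._t_to_z(self.observed_t())

    def rotated_t(self, n_rot: int, rng: np.random.Generator) -> np.ndarray:
        """genes x n_rot matrix of rotated moderated t (cached per seed state)."""
        key = (n_rot, id(rng))
        if key not in self._t_cache:
            dim = self.d + 1
            r = rng.standard_normal((n_rot, dim))
            r /= np.linalg.norm(r, axis=1, keepdims=True)
            effect = self.vectors @ r.T  # genes x n_rot
            total_sq = (self.vectors**2).sum(axis=1, keepdims=True)
            self._t_cache[key] = self._t_scores(effect, np.broadcast_to(total_sq, effect.shape))
        return self._t_cache[key]

    def rotated_z(self, n_rot: int, rng: np.random.Generator) -> np.ndarray:
        """genes x n_rot matrix of rotated normal scores (cached)."""
        key = (n_rot, id(rng))
        if key not in self._z_cache:
            self._z_cache[key] = self._t_to_z(self.rotated_t(n_rot, rng))
        return self._z_cache[key]

    def rotated_ranks(self, n_rot: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Ascending ranks (1..p; p = largest score) of observed and rotated
        statistics.  Ranks are taken on the moderated t itself; the t -> z
        map is strictly increasing, so the ranks coincide with z ranks."""
        key = (n_rot, id(rng))
        if key not in self._rank_cache:
            z_obs = self.observed_t()
            z_rot = self.rotated_t(n_rot, rng)
            allz = np.column_stack([z_obs, z_rot])  # genes x (1 + n_rot)
            order = np.argsort(allz, axis=0, kind="stable")
            ranks = np.empty_like(allz)
            rows = np.arange(1, allz.shape[0] + 1, dtype=float)[:, None]
            np.put_along_axis(ranks, order, np.broadcast_to(rows, allz.shape), axis=0)
            self._rank_cache[key] = (ranks[:, 0], ranks[:, 1:])
        return self._rank_cache[key]

    def member_indices(self, members) -> np.ndarray:
        if not hasattr(self, "_index"):
            self._index = {f: i for i, f in enumerate(self.feature_ids)}
        idx = self._index
        return np.asarray(sorted(idx[m] for m in members if m in idx), dtype=int)


def roast_set_test(ctx: "SetTestContext", members, mirna_id: str) -> SetTestResult:
    """Self-contained rotation test with the unweighted mean normal score."""
    rot = ctx.rotation()
    idx = rot.member_indices(members)
    if idx.size < 2:
        raise ValidationError(f"rotation test needs a set of >=2 genes ({mirna_id!r})")
    if ctx.n_rot < 99:
        raise ValidationError("n_rot must be >= 99")
    obs = float(rot.observed_z()[idx].mean())
    rot_means = rot.rotated_z(ctx.n_rot, ctx.rng)[idx].mean(axis=0)
    b_up = int(np.sum(rot_means >= obs))
    b_down = int(np.sum(rot_means <= obs))
    return SetTestResult(
        mirna_id=mirna_id,
        test_name="roast",
        p_set_up=(1 + b_up) / (ctx.n_rot + 1),
        p_set_down=(1 + b_down) / (ctx.n_rot + 1),
        set_size=int(idx.size),
        complementary=True,
    )


def romer_set_test(ctx: "SetTestContext", members, mirna_id: str) -> SetTestResult:
    """Competitive rotation test on the mean rank of member genes."""
    rot = ctx.rotation()
    idx = rot.member_indices(members)
    if idx.size < 2:
        raise ValidationError(f"rotation test needs a set of >=2 genes ({mirna_id!r})")
    if len(rot.feature_ids) - idx.size < 2:
        raise ValidationError("competitive rotation test needs >=2 genes outside the set")
    if ctx.n_rot < 99:
        raise ValidationError("n_rot must be >= 99")
    obs_ranks, rot_ranks = ctx.rotation().rotated_ranks(ctx.n_rot, ctx.rng)
    obs = float(obs_ranks[idx].mean())
    means = rot_ranks[idx].mean(axis=0)
    # high mean rank = set at the top of the up-regulation ordering
    b_up = int(np.sum(means >= obs))
    b_down = int(np.sum(means <= obs))
    return SetTestResult(
        mirna_id=mirna_id,
        test_name="romer",
        p_set_up=(1 + b_up) / (ctx.n_rot + 1),
        p_set_down=(1 + b_down) / (ctx.n_rot + 1),
        set_size=int(idx.size),
        complementary=True,
    )


# ---------------------------------------------------------------------------
# Context + registry
# ---------------------------------------------------------------------------

@dataclass
class SetTestContext:
    """Shared, lazily-computed state for running one set test over many sets."""

    mrna: ExpressionMatrix
    design: GroupDesign
    mrna_stats: FeatureStats
    rng: np.random.Generator
    n_rot: int = DEFAULT_N_ROT
    n_perm: int = DEFAULT_N_PERM
    tau: float = DEFAULT_TAU
    _ranks: RankData | None = field(default=None, repr=False)
    _rotation: RotationContext | None = field(default=None, repr=False)

    def ranks(self) -> RankData:
        if self._ranks is None:
            self._ranks = rank_by_direction(self.mrna_stats)
        return self._ranks

    def rotation(self) -> RotationContext:
        if self._rotation is None:
            self._rotation = RotationContext(self.mrna, self.design)
        return self._rotation


SetTestFunc = Callable[[SetTestContext, frozenset, str], SetTestResult]

_REGISTRY: dict[str, tuple[SetTestFunc, bool]] = {}


def register_set_test(name: str, func: SetTestFunc, complementary: bool = False) -> None:
    """Register a gene-set test under ``name``.

    ``complementary`` declares whether the test's directional p-values sum
    to one, which selects the combination method downstream.
    """
    _REGISTRY[name] = (func, complementary)


def get_set_test(name: str) -> tuple[SetTestFunc, bool]:
    if name not in _REGISTRY:
        raise ValidationError(
            f"unknown set test {name!r}; available: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def available_set_tests() -> list[str]:
    return sorted(_REGISTRY)


register_set_test("ks", ks_set_test, complementary=False)
register_set_test("wilcoxon", wilcoxon_set_test, complementary=True)
register_set_test("fisher_exact", fisher_exact_set_test, complementary=False)
register_set_test("globalq", global_q_set_test, complementary=False)
register_set_test("roast", roast_set_test, complementary=True)
register_set_test("romer", romer_set_test, complementary=True)
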