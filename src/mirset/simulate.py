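"""Synthetic miRNA/mRNA co-expression generator and FDR/power study driver.

The generator emulates a two-group microarray experiment: log-scale
expression is multivariate normal with lognormally drawn mean vectors and
a block, AR(1) or unstructured (scaled-Wishart) covariance.  A fraction
of miRNAs (10%) and mRNAs (5%) is differentially expressed: a log fold
change delta is added to (half) or subtracted from (other half) the
group-2 mean.  A binary allocation matrix links each miRNA to its target
set (disjoint sets, or a circular chain of overlapping sets), and the
miRNA's group-specific mean degrades its targets' means through a linear
model with strength beta and per-miRNA modification factors, so that a
differential miRNA induces an inverse group shift in its targets.

The study driver repeats this over a grid of fold changes, applies
miRNA-wise, set-wise and combined selection at a Benjamini-Hochberg
level, and reports the mean false-discovery proportion (FDR) and average
power rate (APR) per method and fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GroupDesign, TargetSets, ValidationError
from .combine import bh_adjust, fisher_combine, stouffer_combine, choose_combiner
from .feature import FeatureStats, run_feature_tests
from .settest import SetTestContext, get_set_test

logger = logging.getLogger("mirset")

MEAN_FLOOR = 0.05  # lowest admissible (log-scale) mean after target degradation


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-group experiment."""

    n_per_group: int = 10
    p_mir: int = 200
    p_mrna: int = 2000
    cov_type: str = "block"          # block | ar1 | unstructured
    cov_rho: float = 0.5             # within-block / AR(1) correlation
    block_size: int = 10
    wishart_extra_df: int = 10       # unstructured: df = dim + extra
    sigma_sq: float = 4.0            # noise variance (log2 units squared)
    mean_meanlog: float = 2.0
    mean_sdlog: float = 0.5
    de_prop_mir: float = 0.10
    de_prop_mrna: float = 0.05
    deltas: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    beta: float = 0.5
    factor_mean: float = 1.0
    factor_sd: float = 0.1
    overlap: str = "disjoint"        # disjoint | overlapping
    overlap_fraction: float = 0.5
    set_size_range: tuple[int, int] | None = None  # default depends on overlap mode
    n_runs: int = 100
    alpha: float = 0.05
    n_rot: int = 500
    n_perm: int = 200
    tau: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap not in ("disjoint", "overlapping"):
            raise ValidationError(f"unknown overlap mode {self.overlap!r}")
        if self.cov_type not in ("block", "ar1", "unstructured"):
            raise ValidationError(f"unknown covariance type {self.cov_type!r}")
        for prop in (self.de_prop_mir, self.de_prop_mrna, self.overlap_fraction):
            if not 0.0 <= prop <= 1.0:
                raise ValidationError("proportions must lie in [0, 1]")
        if any(d < 0 for d in self.deltas):
            raise ValidationError("log fold changes must be non-negative")
        if self.set_size_range is None:
            # sizes chosen so the sets tile the default 2000-gene universe:
            # 200 disjoint sets of 10, or 200 half-overlapping sets of 20
            self.set_size_range = (10, 10) if self.overlap == "disjoint" else (20, 20)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(d) - valid
        if unknown:
            raise ValidationError(
                f"invalid config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        d = dict(d)
        for key in ("deltas", "set_size_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Signed DE indicators (+1 up, -1 down, 0 null) and the allocation."""

    de_mir: np.ndarray
    de_mrna: np.ndarray
    sets: TargetSets

    @property
    def n_de_mir(self) -> int:
        return int(np.sum(self.de_mir != 0))


# ---------------------------------------------------------------------------
# Generator pieces
# ---------------------------------------------------------------------------

def make_covariance(
    cov_type: str,
    dim: int,
    rho: float = 0.5,
    block_size: int = 10,
    sigma_sq: float = 1.0,
    wishart_extra_df: int = 10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Symmetric positive-definite covariance of the requested structure."""
    if dim < 1:
        raise ValidationError("dim must be >= 1")
    if cov_type == "ar1":
        if not abs(rho) < 1:
            raise ValidationError("AR(1) needs |rho| < 1")
        idx = np.arange(dim)
        corr = rho ** np.abs(idx[:, None] - idx[None, :])
    elif cov_type == "block":
        if not -1.0 / max(block_size - 1, 1) < rho < 1:
            raise ValidationError("block correlation out of the positive-definite range")
        corr = np.eye(dim)
        for start in range(0, dim, block_size):
            stop = min(start + block_size, dim)
            corr[start:stop, start:stop] = rho
            corr[range(start, stop), range(start, stop)] = 1.0
    elif cov_type == "unstructured":
        if rng is None:
            raise ValidationError("unstructured covariance needs an rng")
        df = dim + wishart_extra_df
        for _ in range(5):
            g = rng.standard_normal((dim, df))
            w = g @ g.T
            sd = np.sqrt(np.diag(w))
            corr = w / np.outer(sd, sd)
            if np.linalg.eigvalsh(corr)[0] > 1e-10:
                break
        else:  # pragma: no cover - Wishart with df >= dim is PD a.s.
            raise ValidationError("failed to generate a positive-definite matrix")
    else:
        raise ValidationError(f"unknown covariance type {cov_type!r}")
    return sigma_sq * corr


def make_allocation(
    p_mir: int,
    p_mrna: int,
    mode: str,
    set_size_range: tuple[int, int],
    overlap_fraction: float,
    rng: np.random.Generator,
    mir_ids: list[str] | None = None,
    mrna_ids: list[str] | None = None,
) -> TargetSets:
    """Build the miRNA -> target-set allocation.

    disjoint: sets partition a subset of the mRNAs (every gene in <=1 set).
    overlapping: a circular chain in which each set shares
    ``round(overlap_fraction * size)`` genes with the next set, so sets of
    differential and null miRNAs necessarily share genes.
    """
    if mir_ids is None:
        mir_ids = default_mir_ids(p_mir)
    if mrna_ids is None:
        mrna_ids = default_mrna_ids(p_mrna)
    lo, hi = set_size_range
    if lo < 2:
        raise ValidationError("set sizes must be >= 2")
    sizes = rng.integers(lo, hi + 1, size=p_mir)
    genes = rng.permutation(np.asarray(mrna_ids))
    sets: dict[str, frozenset[str]] = {}
    if mode == "disjoint":
        if int(sizes.sum()) > p_mrna:
            raise ValidationError(
                f"disjoint sets demand {int(sizes.sum())} genes but only "
                f"{p_mrna} are available"
            )
        pos = 0
        for mir, size in zip(mir_ids, sizes):
            sets[mir] = frozenset(genes[pos:pos + size])
            pos += size
    elif mode == "overlapping":
        shared = np.rint(overlap_fraction * sizes).astype(int)
        own = sizes - shared
        if np.any(own[:-1] < shared[:-1]) or own[-1] < shared[-1]:
            raise ValidationError("overlap fraction too large for the drawn set sizes")
        if int(own.sum()) > p_mrna:
            raise ValidationError(
                f"overlapping sets demand {int(own.sum())} distinct genes but only "
                f"{p_mrna} are available"
            )
        blocks = []
        pos = 0
        for o in own:
            blocks.append(genes[pos:pos + o])
            pos += o
        for i, mir in enumerate(mir_ids):
            nxt = blocks[(i + 1) % p_mir]
            members = np.concatenate([blocks[i], nxt[: shared[i]]])
            sets[mir] = frozenset(members)
    else:
        raise ValidationError(f"unknown allocation mode {mode!r}")
    return TargetSets(sets)


def default_mir_ids(p_mir: int) -> list[str]:
    return [f"mir{i:04d}" for i in range(p_mir)]


def default_mrna_ids(p_mrna: int) -> list[str]:
    return [f"gene{j:05d}" for j in range(p_mrna)]


def select_de(p: int, prop: float, rng: np.random.Generator) -> np.ndarray:
    """Signed DE indicator: round(prop*p) features, half up / half down
    (counts differ by at most one)."""
    n_de = int(round(prop * p))
    signs = np.zeros(p)
    if n_de == 0:
        return signs
    chosen = rng.choice(p, size=n_de, replace=False)
    n_up = n_de // 2 + (n_de % 2)
    signs[chosen[:n_up]] = 1.0
    signs[chosen[n_up:]] = -1.0
    return signs


def inject_de(
    means_g1: np.ndarray, means_g2: np.ndarray, signs: np.ndarray, delta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Add +/- delta to the group-2 means of the selected features."""
    if delta < 0:
        raise ValidationError("delta must be non-negative")
    return means_g1.copy(), means_g2 + signs * delta


def apply_mirna_effect(
    mrna_means: np.ndarray,
    mir_means: np.ndarray,
    allocation: np.ndarray,
    beta: float,
    factors: np.ndarray,
) -> np.ndarray:
    """Degrade target-mRNA means: mu'_j = mu_j - beta * sum_i a_ij c_i mu^mir_i.

    The same per-miRNA factors c_i apply to both groups, so only a
    group-differential miRNA induces a group-differential target shift.
    Resulting means are floored at a small positive constant.
    """
    if beta < 0:
        raise ValidationError("beta must be non-negative")
    degradation = beta * (allocation.T @ (factors * mir_means))
    return np.maximum(mrna_means - degradation, MEAN_FLOOR)


@dataclass
class StudyFixture:
    """Per-study quantities reused across simulation runs: the Cholesky
    factors of the two covariance matrices and the allocation."""

    chol_mir: np.ndarray
    chol_mrna: np.ndarray
    sets: TargetSets
    allocation: np.ndarray
    mir_ids: list[str]
    mrna_ids: list[str]
    sample_ids: list[str]
    design: GroupDesign


def build_fixture(config: SimulationConfig, rng: np.random.Generator) -> StudyFixture:
    mir_ids = default_mir_ids(config.p_mir)
    mrna_ids = default_mrna_ids(config.p_mrna)
    kw = dict(
        rho=config.cov_rho,
        block_size=config.block_size,
        sigma_sq=config.sigma_sq,
        wishart_extra_df=config.wishart_extra_df,
        rng=rng,
    )
    cov_mir = make_covariance(config.cov_type, config.p_mir, **kw)
    cov_mrna = make_covariance(config.cov_type, config.p_mrna, **kw)
    sets = make_allocation(
        config.p_mir, config.p_mrna, config.overlap,
        config.set_size_range, config.overlap_fraction, rng,
        mir_ids=mir_ids, mrna_ids=mrna_ids,
    )
    n = config.n_per_group
    sample_ids = [f"s{k:03d}" for k in range(2 * n)]
    design = GroupDesign({s: (1 if k < n else 2) for k, s in enumerate(sample_ids)})
    return StudyFixture(
        chol_mir=np.linalg.cholesky(cov_mir),
        chol_mrna=np.linalg.cholesky(cov_mrna),
        sets=sets,
        allocation=sets.allocation_matrix(mir_ids, mrna_ids),
        mir_ids=mir_ids,
        mrna_ids=mrna_ids,
        sample_ids=sample_ids,
        design=design,
    )


def draw_dataset(
    config: SimulationConfig,
    rng: np.random.Generator,
    delta: float | None = None,
    fixture: StudyFixture | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroupDesign, TargetSets, SimulationTruth]:
    """Draw one complete synthetic experiment.

    ``fixture`` (covariances + allocation) may be precomputed and shared
    across runs; otherwise it is built here from the same rng.
    """
    if fixture is None:
        fixture = build_fixture(config, rng)
    if delta is None:
        delta = config.deltas[0]
    n = config.n_per_group

    mu_mir = rng.lognormal(config.mean_meanlog, config.mean_sdlog, config.p_mir)
    mu_mrna = rng.lognormal(config.mean_meanlog, config.mean_sdlog, config.p_mrna)
    de_mir = select_de(config.p_mir, config.de_prop_mir, rng)
    de_mrna = select_de(config.p_mrna, config.de_prop_mrna, rng)
    mir_g1, mir_g2 = inject_de(mu_mir, mu_mir, de_mir, delta)
    mrna_g1, mrna_g2 = inject_de(mu_mrna, mu_mrna, de_mrna, delta)
    factors = rng.normal(config.factor_mean, config.factor_sd, config.p_mir)
    mrna_g1 = apply_mirna_effect(mrna_g1, mir_g1, fixture.allocation, config.beta, factors)
    mrna_g2 = apply_mirna_effect(mrna_g2, mir_g2, fixture.allocation, config.beta, factors)

    def sample(chol: np.ndarray, m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
        p = chol.shape[0]
        noise = chol @ rng.standard_normal((p, 2 * n))
        means = np.column_stack([np.tile(m1, (n, 1)).T, np.tile(m2, (n, 1)).T])
        return means + noise

    mirna = ExpressionMatrix(
        sample(fixture.chol_mir, mir_g1, mir_g2), fixture.mir_ids, fixture.sample_ids
    )
    mrna = ExpressionMatrix(
        sample(fixture.chol_mrna, mrna_g1, mrna_g2), fixture.mrna_ids, fixture.sample_ids
    )
    truth = SimulationTruth(de_mir=de_mir, de_mrna=de_mrna, sets=fixture.sets)
    return mirna, mrna, fixture.design, fixture.sets, truth


# ---------------------------------------------------------------------------
# Metrics and study driver
# ---------------------------------------------------------------------------

def evaluate_run(selected: set[str], truth: SimulationTruth, mir_ids: list[str]) -> tuple[float, float]:
    """False-discovery proportion (0/0 := 0) and average power rate."""
    de_ids = {m for m, s in zip(mir_ids, truth.de_mir) if s != 0}
    tp = len(selected & de_ids)
    fp = len(selected) - tp
    fdp = fp / max(1, fp + tp)
    apr = tp / len(de_ids) if de_ids else 0.0
    return float(fdp), float(apr)


def _parse_method(method: str) -> tuple[str, str | None]:
    if method == "mirna_only":
        return "mirna_only", None
    for prefix in ("set_only:", "combined:"):
        if method.startswith(prefix):
            name = method[len(prefix):]
            get_set_test(name)  # raises on unknown test
            return prefix[:-1], name
    raise ValidationError(
        f"unknown method {method!r}; expected 'mirna_only', 'set_only:<test>' "
        "or 'combined:<test>'"
    )


def _run_methods(
    methods: list[str],
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    design: GroupDesign,
    sets: TargetSets,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-method score vector over miRNAs for one simulated dataset."""
    mir_stats = run_feature_tests(mirna, design)
    kinds = [_parse_method(m) for m in methods]
    set_test_names = {name for _, name in kinds if name is not None}
    set_results: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if set_test_names:
        mrna_stats = run_feature_tests(mrna, design)
        ctx = SetTestContext(
            mrna=mrna, design=design, mrna_stats=mrna_stats, rng=rng,
            n_rot=config.n_rot, n_perm=config.n_perm, tau=config.tau,
        )
        for name in sorted(set_test_names):
            func, _ = get_set_test(name)
            p_up = np.empty(len(mirna.feature_ids))
            p_down = np.empty(len(mirna.feature_ids))
            for i, mir in enumerate(mirna.feature_ids):
                res = func(ctx, sets.get(mir), mir)
                p_up[i], p_down[i] = res.p_set_up, res.p_set_down
            set_results[name] = (p_up, p_down)

    scores: dict[str, np.ndarray] = {}
    for method, (kind, name) in zip(methods, kinds):
        if kind == "mirna_only":
            scores[method] = mir_stats.p_two.copy()
        elif kind == "set_only":
            p_up, p_down = set_results[name]
            scores[method] = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
        else:
            p_up, p_down = set_results[name]
            combine = stouffer_combine if choose_combiner(name) == "stouffer" else fisher_combine
            p_comb_up = combine(mir_stats.p_up, p_down)
            p_comb_down = combine(mir_stats.p_down, p_up)
            scores[method] = np.minimum(1.0, 2.0 * np.minimum(p_comb_up, p_comb_down))
    return scores


@dataclass
class SimulationMetrics:
    """Long-format per-(method, delta) metrics plus retained per-run values."""

    long: pd.DataFrame                      # method, delta, fdr, apr, n_runs
    per_run: pd.DataFrame                   # method, delta, run, fdp, apr
    config: SimulationConfig

    def summary(self) -> pd.DataFrame:
        """Min-median-max of mean FDR (and APR) across the delta grid."""
        rows = []
        for method, grp in self.long.groupby("method"):
            rows.append({
                "method": method,
                "fdr_min": grp["fdr"].min(),
                "fdr_median": grp["fdr"].median(),
                "fdr_max": grp["fdr"].max(),
                "apr_min": grp["apr"].min(),
                "apr_median": grp["apr"].median(),
                "apr_max": grp["apr"].max(),
            })
        return pd.DataFrame(rows)


def run_study(
    config: SimulationConfig,
    methods: list[str],
    flush_path: str | None = None,
    progress: bool = False,
) -> SimulationMetrics:
    """Run the full FDR/APR evaluation.

    All requested methods are evaluated on the same dataset within each
    run (a paired comparison).  With ``flush_path`` the per-run rows are
    appended to a TSV after every run so an interrupted study leaves
    partial results behind.
    """
    for m in methods:
        _parse_method(m)
    rng = np.random.default_rng(config.seed)
    fixture = build_fixture(config, rng)
    records: list[dict] = []
    flush_fh = open(flush_path, "w") if flush_path else None
    if flush_fh:
        flush_fh.write("method\tdelta\trun\tfdp\tapr\n")
    try:
        for delta in config.deltas:
            for run in range(config.n_runs):
                mirna, mrna, design, sets, truth = draw_dataset(
                    config, rng, delta=delta, fixture=fixture
                )
                score_by_method = _run_methods(
                    methods, mirna, mrna, design, sets, config, rng
                )
                for method, score in score_by_method.items():
                    adj = bh_adjust(score)
                    selected = {
                        mir for mir, q in zip(fixture.mir_ids, adj)
                        if q <= config.alpha
                    }
                    fdp, apr = evaluate_run(selected, truth, fixture.mir_ids)
                    records.append({
                        "method": method, "delta": delta, "run": run,
                        "fdp": fdp, "apr": apr,
                    })
                    if flush_fh:
                        flush_fh.write(f"{method}\t{delta}\t{run}\t{fdp}\t{apr}\n")
                if flush_fh:
                    flush_fh.flush()
            if progress:
                logger.info("run_study: finished delta=%s (%d runs)", delta, config.n_runs)
    finally:
        if flush_fh:
            flush_fh.close()
    per_run = pd.DataFrame(records)
    long = (
        per_run.groupby(["method", "delta"], as_index=False)
        .agg(fdr=("fdp", "mean"), apr=("apr", "mean"), n_runs=("run", "size"))
    )
    return SimulationMetrics(long=long, per_run=per_run, config=config)
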