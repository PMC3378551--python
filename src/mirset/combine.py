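"""Meta-analytic combination of miRNA-wise and target-set p-values.

A miRNA is expected to act inversely on its targets, so the miRNA's
up-regulation p-value is combined with the set's down-regulation p-value
and vice versa.  Tests whose directional set p-values sum to one
(Wilcoxon and the two rotation tests) are combined with Stouffer's
inverse-normal method; all others use Fisher's method against a
chi-square distribution with four degrees of freedom.  The final score

    q = min(1, 2 * min(p_comb_up, p_comb_down))

lies in [0, 1]; under Stouffer+Wilcoxon it behaves like a genuine
two-sided p-value, while rotation-based scores are slightly conservative.
Scores are adjusted across miRNAs with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GroupDesign, TargetSets, ValidationError
from .feature import FeatureStats, run_feature_tests
from .settest import SetTestContext, SetTestResult, get_set_test

logger = logging.getLogger("mirset")

P_EPS = 1e-300  # clipping for zeros before logs / normal quantiles


@dataclass
class CombinedResult:
    mirna_id: str
    set_size: int
    p_mir_up: float
    p_mir_down: float
    p_set_up: float
    p_set_down: float
    p_comb_up: float
    p_comb_down: float
    score: float
    method: str
    flag: str = ""  # "no_set" marks miRNA-only fallback rows


def choose_combiner(test_name: str) -> str:
    """'stouffer' for tests with complementary directional p-values,
    'fisher' otherwise."""
    _, complementary = get_set_test(test_name)
    return "stouffer" if complementary else "fisher"


def _check_p(p, name: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if np.any(np.isnan(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError(f"{name} = {p!r} is not a probability")
    return np.clip(arr, P_EPS, 1.0)


def fisher_combine(p_a, p_b):
    """Fisher's method for two p-values: -2(ln p_a + ln p_b) ~ chi2(4).

    Accepts scalars or arrays (elementwise); symmetric and monotone
    non-decreasing in each argument.
    """
    a = _check_p(p_a, "p_a")
    b = _check_p(p_b, "p_b")
    c = -2.0 * (np.log(a) + np.log(b))
    out = stats.chi2.sf(c, df=4)
    return float(out) if np.isscalar(p_a) and np.isscalar(p_b) else out


def stouffer_combine(p_a, p_b):
    """Stouffer's inverse-normal method for two p-values (scalars or arrays)."""
    a = np.minimum(_check_p(p_a, "p_a"), 1 - 1e-16)
    b = np.minimum(_check_p(p_b, "p_b"), 1 - 1e-16)
    z = (stats.norm.isf(a) + stats.norm.isf(b)) / math.sqrt(2.0)
    out = stats.norm.sf(z)
    return float(out) if np.isscalar(p_a) and np.isscalar(p_b) else out


_COMBINERS = {"fisher": fisher_combine, "stouffer": stouffer_combine}


def combine_directions(
    mirna_id: str,
    p_mir_up: float,
    p_mir_down: float,
    set_result: SetTestResult,
    method: str,
) -> CombinedResult:
    """Pair miRNA-up with set-down (and vice versa) and derive the score."""
    combine = _COMBINERS[method]
    p_comb_up = combine(p_mir_up, set_result.p_set_down)
    p_comb_down = combine(p_mir_down, set_result.p_set_up)
    score = min(1.0, 2.0 * min(p_comb_up, p_comb_down))
    return CombinedResult(
        mirna_id=mirna_id,
        set_size=set_result.set_size,
        p_mir_up=p_mir_up,
        p_mir_down=p_mir_down,
        p_set_up=set_result.p_set_up,
        p_set_down=set_result.p_set_down,
        p_comb_up=p_comb_up,
        p_comb_down=p_comb_down,
        score=score,
        method=method,
    )


def bh_adjust(scores: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(scores, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d array")
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_pipeline(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    design: GroupDesign,
    sets: TargetSets,
    set_test: str = "romer",
    n_rot: int = 1000,
    n_perm: int = 1000,
    tau: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mirna_stats: FeatureStats | None = None,
    mrna_stats: FeatureStats | None = None,
) -> pd.DataFrame:
    """Full analysis: feature tests on both matrices, one set test per
    miRNA's target set, p-value combination, and BH adjustment.

    miRNAs without a testable set are kept with a miRNA-only score
    (two-sided moderated-t p) and flagged ``no_set``.
    """
    test_func, _ = get_set_test(set_test)
    method = choose_combiner(set_test)
    if rng is None:
        rng = np.random.default_rng(seed)
    if mirna_stats is None:
        mirna_stats = run_feature_tests(mirna, design)
    if mrna_stats is None:
        mrna_stats = run_feature_tests(mrna, design)
    ctx = SetTestContext(
        mrna=mrna, design=design, mrna_stats=mrna_stats,
        rng=rng, n_rot=n_rot, n_perm=n_perm, tau=tau,
    )
    rows: list[CombinedResult] = []
    for i, mir in enumerate(mirna.feature_ids):
        p_up = float(mirna_stats.p_up[i])
        p_down = float(mirna_stats.p_down[i])
        members = sets.get(mir)
        if members:
            set_res = test_func(ctx, members, mir)
            rows.append(combine_directions(mir, p_up, p_down, set_res, method))
        else:
            rows.append(CombinedResult(
                mirna_id=mir, set_size=0,
                p_mir_up=p_up, p_mir_down=p_down,
                p_set_up=float("nan"), p_set_down=float("nan"),
                p_comb_up=float("nan"), p_comb_down=float("nan"),
                score=float(mirna_stats.p_two[i]),
                method="mirna_only", flag="no_set",
            ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["score_adj"] = bh_adjust(df["score"].to_numpy())
    n_flagged = int((df["flag"] == "no_set").sum())
    if n_flagged:
        logger.info("run_pipeline: %d miRNAs without a testable set (flagged)", n_flagged)
    return df
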