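"""Domain containers, file readers/writers and preprocessing.

The pipeline works on two log-scale expression matrices (miRNA and mRNA,
features x samples), a two-level group assignment, and a collection of
miRNA -> target-mRNA sets (equivalently a binary allocation matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("mirset")

DEFAULT_MIN_SET_SIZE = 2


class ValidationError(ValueError):
    """Input violates a structural requirement (ids, dimensions, finiteness)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, features in rows, samples in columns."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-d matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class GroupDesign:
    """Two-group sample assignment; group labels are 1 and 2.

    The reference group is group 1: "up-regulated" throughout the package
    means a higher mean in group 2.
    """

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        bad = {g for g in self.assignment.values() if g not in (1, 2)}
        if bad:
            raise ValidationError(f"group labels must be 1 or 2, got {sorted(bad)}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError(
                f"each group needs >=2 samples (got n1={self.n1}, n2={self.n2})"
            )

    @property
    def n1(self) -> int:
        return sum(1 for g in self.assignment.values() if g == 1)

    @property
    def n2(self) -> int:
        return sum(1 for g in self.assignment.values() if g == 2)

    def indicator(self, sample_ids: Iterable[str]) -> np.ndarray:
        """0/1 vector over sample_ids: 1 marks group 2."""
        out = []
        for s in sample_ids:
            if s not in self.assignment:
                raise ValidationError(f"sample {s!r} has no group assignment")
            out.append(self.assignment[s] - 1)
        return np.asarray(out, dtype=float)


@dataclass
class TargetSets:
    """Mapping miRNA id -> set of target mRNA ids (allocation matrix a_ij)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {str(k): frozenset(map(str, v)) for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.sets

    def get(self, mirna: str) -> frozenset[str] | None:
        return self.sets.get(mirna)

    def allocation_matrix(self, mirna_ids: list[str], mrna_ids: list[str]) -> np.ndarray:
        """Dense 0/1 matrix A with a_ij = 1 iff miRNA i targets mRNA j."""
        col = {m: j for j, m in enumerate(mrna_ids)}
        a = np.zeros((len(mirna_ids), len(mrna_ids)))
        for i, mir in enumerate(mirna_ids):
            for g in self.sets.get(mir, ()):  # genes outside the universe ignored
                if g in col:
                    a[i, col[g]] = 1.0
        return a


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} id {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(path: str) -> ExpressionMatrix:
    """Read a tab-separated expression table (first column feature ids,
    header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    feature_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric value {raw[i, j]!r} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(values, feature_ids, sample_ids)


def write_expression_table(x: ExpressionMatrix, path: str) -> None:
    x.to_frame().to_csv(path, sep="\t", index_label="feature")


def read_groups(path: str) -> GroupDesign:
    """Two-column TSV: sample_id TAB group (1 or 2)."""
    assignment: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sample, grp = parts
            if sample in assignment:
                raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
            try:
                assignment[sample] = int(grp)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: group label {grp!r} is not an integer"
                ) from None
    return GroupDesign(assignment)


def read_gmt(path: str, min_set_size: int = DEFAULT_MIN_SET_SIZE) -> tuple[TargetSets, int]:
    """Read a GMT file (set name, description, members...).

    Sets with fewer than ``min_set_size`` distinct members are dropped.
    Returns the retained sets and the number of dropped sets.
    """
    sets: dict[str, frozenset[str]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=2 fields")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in parts[2:] if m)
            if len(members) < min_set_size:
                dropped += 1
                continue
            sets[name] = members
    if dropped:
        logger.info("read_gmt: dropped %d sets smaller than %d", dropped, min_set_size)
    return TargetSets(sets), dropped


def write_gmt(sets: TargetSets, path: str) -> None:
    with open(path, "w") as fh:
        for name in sets.sets:
            members = sorted(sets.sets[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_allocation_matrix(path: str, min_set_size: int = DEFAULT_MIN_SET_SIZE) -> tuple[TargetSets, int]:
    """Dense 0/1 TSV, miRNAs in rows, mRNAs in columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ParseError(f"{path}: allocation matrix entries must be 0 or 1")
    mrna_ids = np.asarray([str(c) for c in df.columns])
    sets = {}
    dropped = 0
    for i, mir in enumerate(df.index):
        members = frozenset(mrna_ids[vals[i] == 1])
        if len(members) < min_set_size:
            dropped += 1
            continue
        sets[str(mir)] = members
    return TargetSets(sets), dropped


def intersect_universe(
    sets: TargetSets,
    mrna: ExpressionMatrix,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> TargetSets:
    """Restrict target sets to the measured mRNA universe; drop sets that
    fall below ``min_set_size`` afterwards.

    Idempotent; raises if no set survives.
    """
    universe = set(mrna.feature_ids)
    kept: dict[str, frozenset[str]] = {}
    removed = 0
    for mir, members in sets.sets.items():
        inter = members & universe
        if len(inter) >= min_set_size:
            kept[mir] = frozenset(inter)
        else:
            removed += 1
    if removed:
        logger.info("intersect_universe: removed %d sets below size %d", removed, min_set_size)
    if not kept:
        raise ValidationError("no testable sets after intersection with the mRNA universe")
    return TargetSets(kept)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def log2_quantile_normalize(x: ExpressionMatrix, log_transform: bool = True) -> ExpressionMatrix:
    """Optional log2 transform followed by quantile normalization.

    After normalization every column holds the identical multiset of values:
    the across-column means of the order statistics. Within-column ties get
    the mean of their candidate normalized values, so the result is
    deterministic and symmetric in tied entries.
    """
    v = x.values
    if log_transform:
        if np.any(v <= 0):
            raise ValidationError("log2 transform requires strictly positive values")
        v = np.log2(v)
    order = np.argsort(v, axis=0, kind="stable")
    sorted_v = np.take_along_axis(v, order, axis=0)
    ref = sorted_v.mean(axis=1)  # mean order statistics across columns
    out = np.empty_like(v)
    n = v.shape[0]
    for j in range(v.shape[1]):
        col = np.empty(n)
        col[order[:, j]] = ref
        # average candidate values over within-column ties
        uniq, inv = np.unique(v[:, j], return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[:, j] = col
    return ExpressionMatrix(out, list(x.feature_ids), list(x.sample_ids))
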