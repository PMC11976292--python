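"""E-locus definition, epiallele pattern counting and disorder statistics.

An e-locus is a window of four adjacent CpGs close enough to be phased on a
single bisulfite read.  Each read covering all four CpGs exhibits one of 16
binary methylation patterns (epialleles).  From the per-sample pattern
counts two summary statistics are computed:

* ``epipolymorphism`` -- the probability that two epialleles drawn at
  random (with replacement) from the locus differ: ``1 - sum(p_i^2)``,
  bounded above by 15/16 = 0.9375;
* ``avg_methylation`` -- the read-weighted mean methylated fraction over
  the four CpGs.

The module also implements the standard locus-level filters applied before
any downstream testing: removal of CpGs at SNP sites and retention of
e-loci covered at >= ``min_depth`` in >= ``min_sample_fraction`` of
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CPGS = 4
N_PATTERNS = 1 << N_CPGS  # 16
#: Maximum attainable epipolymorphism, reached when all 16 patterns are
#: equiprobable: 1 - 16 * (1/16)^2.
MAX_EPIPOLYMORPHISM = 1.0 - N_PATTERNS * (1.0 / N_PATTERNS) ** 2

#: Number of methylated CpGs encoded by each pattern code (bit 3 = 5'-most CpG).
PATTERN_WEIGHTS = np.array(
    [bin(code).count("1") for code in range(N_PATTERNS)], dtype=float
)


@dataclass(frozen=True)
class ELocus:
    """A window of exactly four CpGs on one chromosome.

    ``positions`` are 0-based plus-strand C coordinates in strictly
    ascending order; ``span`` is the distance from first to last CpG.
    """

    id: str
    chrom: str
    positions: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.positions) != N_CPGS:
            raise ValueError(f"e-locus needs exactly {N_CPGS} CpGs")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("CpG positions must be unique and ascending")

    @property
    def span(self) -> int:
        return self.positions[-1] - self.positions[0]


def pattern_code(calls: Sequence[int]) -> int:
    """Encode four binary calls (5'->3') as a pattern code 0-15.

    The 5'-most CpG maps to the most significant bit, so all-methylated
    reads are pattern 15 and all-unmethylated reads pattern 0.
    """
    if len(calls) != N_CPGS:
        raise ValueError("expected 4 calls")
    code = 0
    for c in calls:
        if c not in (0, 1):
            raise ValueError(f"call must be 0 or 1, got {c!r}")
        code = (code << 1) | int(c)
    return code


def decode_pattern(code: int) -> tuple[int, int, int, int]:
    """Inverse of :func:`pattern_code`."""
    return tuple((code >> (N_CPGS - 1 - i)) & 1 for i in range(N_CPGS))  # type: ignore[return-value]


def enumerate_eloci(
    cpg_positions: Mapping[str, Sequence[int]], max_span: int = 100
) -> list[ELocus]:
    """Slide a 4-CpG window (step one CpG) over each chromosome.

    Every run of four consecutive CpGs whose span (last - first) does not
    exceed ``max_span`` becomes one e-locus; overlapping windows are
    allowed.  Ids are deterministic: ``chrom:pos1-pos4``.

    Raises ``ValueError`` if positions are unsorted or duplicated.
    """
    eloci: list[ELocus] = []
    for chrom in sorted(cpg_positions):
        pos = np.asarray(cpg_positions[chrom], dtype=np.int64)
        if pos.size and (np.any(np.diff(pos) <= 0)):
            raise ValueError(f"CpG positions on {chrom} must be sorted and unique")
        for i in range(pos.size - N_CPGS + 1):
            window = pos[i : i + N_CPGS]
            if window[-1] - window[0] <= max_span:
                eloci.append(
                    ELocus(
                        id=f"{chrom}:{window[0]}-{window[-1]}",
                        chrom=chrom,
                        positions=tuple(int(p) for p in window),
                    )
                )
    return eloci


def remove_snp_cpgs(
    cpg_positions: Mapping[str, Sequence[int]],
    snp_sites: Mapping[str, Iterable[int]] | pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Drop CpGs whose coordinate falls at a SNP site.

    ``snp_sites`` is either a mapping chrom -> iterable of 0-based
    positions, or a BED-style DataFrame with columns ``chrom``, ``start``,
    ``end`` (0-based half-open intervals).  An empty SNP set is the
    identity.
    """
    blocked: dict[str, set[int]] = {}
    if isinstance(snp_sites, pd.DataFrame):
        for row in snp_sites.itertuples(index=False):
            blocked.setdefault(str(row.chrom), set()).update(
                range(int(row.start), int(row.end))
            )
    else:
        for chrom, sites in snp_sites.items():
            blocked.setdefault(str(chrom), set()).update(int(s) for s in sites)
    out: dict[str, np.ndarray] = {}
    for chrom, pos in cpg_positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        bad = blocked.get(chrom, set())
        keep = np.array([p not in bad for p in pos], dtype=bool)
        out[chrom] = pos[keep]
    return out


def count_patterns(
    read_calls: pd.DataFrame,
    eloci: Sequence[ELocus],
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Count epiallele patterns per (e-locus, sample) from read-level calls.

    ``read_calls`` holds one row per (read, CpG): columns ``read_id``,
    ``chrom``, ``pos`` (0-based), ``call`` in {0, 1} and optionally a
    sample column.  A read contributes to an e-locus only when it carries
    a definite call at all four CpGs; partial or ambiguous reads are
    excluded (and logged).  Reads may contribute to several overlapping
    e-loci.

    Returns a DataFrame indexed by (elocus_id, sample_id) with 16 integer
    count columns ``0``..``15`` ordered by pattern code.
    """
    calls = read_calls.copy()
    if sample_col not in calls.columns:
        calls[sample_col] = "sample"
    bad = ~calls["call"].isin([0, 1])
    if bad.any():
        logger.warning("excluding %d ambiguous calls", int(bad.sum()))
        calls = calls[~bad]

    # map (chrom, pos) -> list of (elocus_id, slot index within the window)
    slot_rows = []
    for el in eloci:
        for j, p in enumerate(el.positions):
            slot_rows.append((el.chrom, p, el.id, j))
    slots = pd.DataFrame(slot_rows, columns=["chrom", "pos", "elocus_id", "slot"])

    merged = calls.merge(slots, on=["chrom", "pos"], how="inner")
    if merged.empty:
        return pd.DataFrame(
            columns=list(range(N_PATTERNS)),
            index=pd.MultiIndex.from_arrays([[], []], names=["elocus_id", sample_col]),
            dtype=int,
        )

    # keep only (read, e-locus) groups with all four slots called
    grp = merged.groupby(["elocus_id", sample_col, "read_id"], sort=False)
    n_slots = grp["slot"].transform("nunique")
    complete = merged[n_slots == N_CPGS]
    n_dropped = grp.ngroups - complete.groupby(
        ["elocus_id", sample_col, "read_id"], sort=False
    ).ngroups
    if n_dropped:
        logger.info("excluded %d read/e-locus combinations with partial coverage", n_dropped)

    bitvals = (1 << (N_CPGS - 1 - complete["slot"].to_numpy())) * complete[
        "call"
    ].to_numpy()
    codes = (
        pd.Series(bitvals, index=complete.index)
        .groupby(
            [complete["elocus_id"], complete[sample_col], complete["read_id"]],
            sort=False,
        )
        .sum()
    )
    counts = (
        codes.groupby(level=["elocus_id", sample_col])
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=range(N_PATTERNS), fill_value=0)
        .astype(int)
    )
    counts.index.names = ["elocus_id", sample_col]
    counts.columns = list(range(N_PATTERNS))
    return counts


def epipolymorphism(counts) -> np.ndarray | float:
    """Epipolymorphism ``1 - sum(p_i^2)`` of a 16-pattern count vector.

    Accepts any array whose last axis has length 16; returns NaN where the
    depth is zero (a locus absent from a sample carries no information and
    must not masquerade as perfectly ordered).
    """
    c = np.asarray(counts, dtype=float)
    if c.shape[-1] != N_PATTERNS:
        raise ValueError("last axis must have length 16")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    depth = c.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = c / depth[..., None]
        val = 1.0 - np.sum(p * p, axis=-1)
    val = np.where(depth > 0, val, np.nan)
    return float(val) if val.ndim == 0 else val


def avg_methylation(counts) -> np.ndarray | float:
    """Mean methylated fraction over the four CpGs, read-weighted.

    Equals ``sum(p_i * popcount(i) / 4)``; identical to averaging the four
    per-CpG methylated fractions.  NaN at zero depth.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape[-1] != N_PATTERNS:
        raise ValueError("last axis must have length 16")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    depth = c.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = (c @ PATTERN_WEIGHTS) / (N_CPGS * depth)
    val = np.where(depth > 0, val, np.nan)
    return float(val) if val.ndim == 0 else val


def profiles_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Turn a pattern-count table into an e-locus profile table.

    Input is the output of :func:`count_patterns` (MultiIndex
    (elocus_id, sample_id), 16 count columns).  Output columns:
    ``elocus_id``, ``sample_id``, ``epipolymorphism``, ``avg_methylation``,
    ``depth``.
    """
    arr = counts.to_numpy(dtype=float)
    out = counts.index.to_frame(index=False)
    out.columns = ["elocus_id", "sample_id"]
    out["epipolymorphism"] = epipolymorphism(arr)
    out["avg_methylation"] = avg_methylation(arr)
    out["depth"] = arr.sum(axis=1).astype(int)
    return out


def filter_eloci(
    profiles: pd.DataFrame,
    min_depth: int = 10,
    min_sample_fraction: float = 0.75,
    samples: Sequence[str] | None = None,
) -> list[str]:
    """Retain e-loci measured at >= ``min_depth`` in enough samples.

    An e-locus passes when the fraction of samples with depth >=
    ``min_depth`` is >= ``min_sample_fraction`` (boundary inclusive:
    exactly 75% passes under the defaults).  Samples absent from the
    profile table for a locus count as depth 0.  ``samples`` fixes the
    sample universe; by default it is every sample present in the table.
    """
    if samples is None:
        samples = profiles["sample_id"].unique().tolist()
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("empty sample set")
    sub = profiles[profiles["sample_id"].isin(set(samples))]
    deep = sub[sub["depth"] >= min_depth]
    n_deep = deep.groupby("elocus_id", sort=False)["sample_id"].nunique()
    keep = n_deep[n_deep / n_samples >= min_sample_fraction]
    return keep.index.tolist()
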