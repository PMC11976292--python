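"""Readers/writers for the pipeline's file formats and run configuration.

Internal coordinates are uniformly 0-based half-open; the 1-based CpG
report dialect is shifted on input.  Every table written by the pipeline
carries header comment lines (``# key: value``) recording the tool
version, seed and effective thresholds, which readers skip.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective thresholds and paths of one analysis run.

    The defaults are the analysis' canonical thresholds: significance
    requires |delta epipolymorphism| > 0.1 and BH-adjusted p < 0.01;
    e-loci must be covered at >= 10x in >= 75% of samples; variance
    selection keeps the top 10% of features; the nested-model q cut-off
    is 0.05; PCAR homogeneity means a maximum relative difference < 30%.
    """

    seed: int = 0
    delta_min: float = 0.1
    alpha: float = 0.01
    min_depth: int = 10
    min_sample_fraction: float = 0.75
    variance_fraction: float = 0.10
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    q_threshold: float = 0.05
    pcar_bound: float = 0.30
    max_span: int = 100
    test: str = "permutation"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write_effective(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def table_header(seed: int | None = None, **params) -> str:
    """Header comment block recording provenance for an output table."""
    from . import __version__

    lines = [f"# methylhet version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for key in sorted(params):
        lines.append(f"# {key}: {params[key]}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                index: bool = False, **params) -> None:
    """Write a TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(table_header(seed=seed, **params))
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col,
                       na_values=["NA"])


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read per-CpG counts from a 4+2-column bedGraph.

    Columns: chrom, start, end, methylation %, count methylated, count
    unmethylated; 0-based half-open.  Returns a DataFrame (chrom, pos,
    count_m, count_u) with ``pos`` the 0-based C coordinate.
    """
    df = _read_counts_file(path, n_cols=6)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "pos", "count_m", "count_u"])
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "pos": df[1].astype(int),
            "count_m": df[4].astype(int),
            "count_u": df[5].astype(int),
        }
    )
    _check_counts(out)
    return out


def read_cpg_report(path: str | Path) -> pd.DataFrame:
    """Read a Bismark-style CpG report (1-based positions).

    Columns: chrom, pos (1-based), strand, count methylated, count
    unmethylated, context, trinucleotide.  Positions are shifted to the
    internal 0-based convention.
    """
    df = _read_counts_file(path, n_cols=7)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "pos", "count_m", "count_u"])
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "pos": df[1].astype(int) - 1,
            "count_m": df[3].astype(int),
            "count_u": df[4].astype(int),
        }
    )
    _check_counts(out)
    return out


def read_cpg_counts(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read per-CpG counts, auto-detecting bedGraph vs CpG-report dialect.

    Detection is by column count (6 vs 7); ``dialect`` in
    {"bedgraph", "cpg_report"} overrides it.
    """
    if dialect == "bedgraph":
        return read_bedgraph(path)
    if dialect == "cpg_report":
        return read_cpg_report(path)
    if dialect != "auto":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track")):
                n = len(line.rstrip("\n").split("\t"))
                break
        else:
            logger.warning("empty counts file %s", path)
            return pd.DataFrame(columns=["chrom", "pos", "count_m", "count_u"])
    if n == 6:
        return read_bedgraph(path)
    if n == 7:
        return read_cpg_report(path)
    raise ValueError(f"cannot detect dialect of {path}: {n} columns")


def _read_counts_file(path: str | Path, n_cols: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            rows.append(parts)
    if not rows:
        logger.warning("empty counts file %s", path)
        return pd.DataFrame()
    return pd.DataFrame(rows)


def _check_counts(df: pd.DataFrame) -> None:
    if (df[["count_m", "count_u"]] < 0).any().any():
        raise ValueError("negative counts")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end); 0-based half-open.

    Malformed lines are reported with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree (branch lengths and quoted labels supported)."""
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with %.6g branch lengths (round-trip stable)."""
    s = tree.as_string(
        schema="newick",
        real_value_format_specifier=".6g",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
    with open(path, "w") as fh:
        fh.write(s)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labelled matrix TSV (first column = row ids, NA = missing)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#",
                       na_values=["NA"])


def write_matrix_tsv(df: pd.DataFrame, path: str | Path,
                     seed: int | None = None, **params) -> None:
    """Write a labelled matrix TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(table_header(seed=seed, **params))
        df.to_csv(fh, sep="\t", na_rep="NA")


def write_read_patterns(
    sim, path: str | Path, max_loci: int | None = None, seed: int | None = None
) -> None:
    """Write simulated epiallele counts as a read-level call TSV.

    Each simulated read becomes four rows (read_id, sample_id, chrom, pos,
    call), the format :func:`methylhet.epiallele.count_patterns` consumes.
    ``max_loci`` truncates output for toy fixtures.
    """
    from .epiallele import decode_pattern

    eloci = sim.eloci if max_loci is None else sim.eloci[:max_loci]
    with open(path, "w") as fh:
        fh.write(table_header(seed=seed))
        fh.write("read_id\tsample_id\tchrom\tpos\tcall\n")
        for li, el in enumerate(eloci):
            for si, sample in enumerate(sim.samples["sample_id"]):
                read_no = 0
                for code in range(16):
                    for _ in range(int(sim.counts[li, si, code])):
                        read_no += 1
                        rid = f"r_{el.id}_{sample}_{read_no}"
                        for pos, call in zip(el.positions, decode_pattern(code)):
                            fh.write(f"{rid}\t{sample}\t{el.chrom}\t{pos}\t{call}\n")
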