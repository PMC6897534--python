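"""Table and sequence I/O for clone-tracing and screen data.

Count tables are held as pandas DataFrames indexed by barcode (or sgRNA id)
with one integer column per sample.  Screen tables additionally carry
``gene``/``tss`` annotation columns and a ``targeting`` flag.  Raw
clone-tracing reads are filtered on barcode pattern conformity: the tags are
30 nt of strictly alternating weak (A/T) then strong (G/C) bases, which
makes true barcodes cheap to recognize without alignment.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml

ANNOTATION_COLS = ["gene", "tss", "targeting"]
WEAK = frozenset("AT")
STRONG = frozenset("GC")


@dataclass
class SampleSheet:
    """Per-sample metadata mapping count columns to experimental roles.

    ``samples`` maps sample_id -> dict with keys ``drug`` (text; "DMSO" or
    "HCS" denote vehicle), ``replicate`` (int >= 1), ``timepoint`` (one of
    pretreatment/post_treatment/T0/vehicle_end/treated_end) and optionally
    ``doublings`` (population doublings relative to the paired reference)
    and ``reference`` (the matching vehicle sample for treated_end samples).
    """

    samples: dict[str, dict] = field(default_factory=dict)

    TIMEPOINTS = {"pretreatment", "post_treatment", "T0", "vehicle_end",
                  "treated_end"}

    def __post_init__(self) -> None:
        for sid, meta in self.samples.items():
            tp = meta.get("timepoint")
            if tp not in self.TIMEPOINTS:
                raise ValueError(f"sample {sid!r}: unknown timepoint {tp!r}")
            rep = meta.get("replicate", 1)
            if int(rep) < 1:
                raise ValueError(f"sample {sid!r}: replicate must be >= 1")
            d = meta.get("doublings")
            if d is not None and not np.isfinite(d):
                raise ValueError(f"sample {sid!r}: doublings must be finite")
            if tp == "treated_end":
                ref = meta.get("reference")
                if ref is not None and ref not in self.samples:
                    raise ValueError(
                        f"sample {sid!r}: reference {ref!r} not in sheet")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleSheet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(samples=data["samples"])

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"samples": self.samples}, fh, sort_keys=True)

    def by_drug(self, timepoint: str = "post_treatment") -> dict[str, list[str]]:
        """Sample ids per drug at a timepoint, ordered by replicate."""
        out: dict[str, list[tuple[int, str]]] = {}
        for sid, meta in self.samples.items():
            if meta["timepoint"] == timepoint:
                out.setdefault(meta["drug"], []).append(
                    (int(meta.get("replicate", 1)), sid))
        return {d: [s for _, s in sorted(v)] for d, v in out.items()}


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_count_table(
    path: str | Path,
    schema: Literal["barcode", "sgrna"] = "barcode",
) -> pd.DataFrame:
    """Read a delimited count table (tab or comma; auto-detected).

    ``barcode`` schema: first column is the barcode id, all other columns
    integer counts per sample.  ``sgrna`` schema: columns
    sgrna_id, gene, tss, targeting, then counts.  Raises on duplicate ids,
    missing cells, or non-integer/negative counts, naming the offender.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample columns in header")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in column {id_col!r}")
    df = df.set_index(id_col)
    df.index.name = "sgrna_id" if schema == "sgrna" else "barcode"

    if schema == "sgrna":
        missing = [c for c in ANNOTATION_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"sgrna table missing columns: {missing}")
        count_cols = [c for c in df.columns if c not in ANNOTATION_COLS]
    else:
        count_cols = list(df.columns)

    for col in count_cols:
        vals = df[col]
        if vals.isna().any():
            row = vals.index[vals.isna()][0]
            raise ValueError(f"missing count at row {row!r}, column {col!r}")
        try:
            as_num = pd.to_numeric(vals)
        except (ValueError, TypeError) as exc:
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
            raise ValueError(
                f"malformed count at row {bad.index[0]!r}, column {col!r}:"
                f" {bad.iloc[0]!r}") from exc
        if (as_num < 0).any():
            row = as_num.index[as_num < 0][0]
            raise ValueError(
                f"negative count at row {row!r}, column {col!r}")
        if (as_num != as_num.astype(np.int64)).any():
            row = as_num.index[(as_num != as_num.astype(np.int64))][0]
            raise ValueError(
                f"non-integer count at row {row!r}, column {col!r}")
        df[col] = as_num.astype(np.int64)

    if schema == "sgrna":
        df["targeting"] = df["targeting"].astype(str).str.lower().isin(
            {"true", "1", "yes", "targeting"})
    return df


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a count table as tab-delimited text (round-trips with read)."""
    table.to_csv(path, sep="\t")


def count_columns(table: pd.DataFrame) -> list[str]:
    """Names of the count (sample) columns of either table schema."""
    return [c for c in table.columns if c not in ANNOTATION_COLS]


def is_valid_barcode(seq: str, pattern_length: int = 30) -> bool:
    """True if the first ``pattern_length`` bases strictly alternate
    weak (A/T) at odd positions then strong (G/C) at even positions,
    starting weak at position 1."""
    if len(seq) < pattern_length:
        return False
    seq = seq[:pattern_length].upper()
    for i, base in enumerate(seq):
        if base not in (WEAK if i % 2 == 0 else STRONG):
            return False
    return True


def extract_barcodes(
    reads: Iterable[str],
    pattern_length: int = 30,
) -> tuple[pd.DataFrame, int]:
    """Count pattern-conforming barcodes among raw read sequences.

    ``reads`` are sequences already trimmed to begin at the barcode
    (see :func:`read_fastq_sequences`).  Returns a one-column count table
    and the number of discarded (non-conforming) reads.  Quality scores are
    ignored; the alternating weak/strong pattern is the only filter.
    """
    counts: Counter[str] = Counter()
    discarded = 0
    total = 0
    for seq in reads:
        total += 1
        if is_valid_barcode(seq, pattern_length):
            counts[str(seq)[:pattern_length].upper()] += 1
        else:
            discarded += 1
    if total == 0:
        import warnings

        warnings.warn("extract_barcodes received zero reads", stacklevel=2)
    table = pd.DataFrame(
        {"reads": pd.Series(dict(sorted(counts.items())), dtype=np.int64)})
    table.index.name = "barcode"
    return table, discarded


def read_fastq_sequences(path: str | Path) -> Iterable[str]:
    """Yield read sequences from a FASTQ file (4-line records)."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _neighbor_candidates(barcodes: list[str], max_hamming: int):
    """Candidate close pairs via a pigeonhole index on sequence slices.

    Splitting each barcode into ``max_hamming + 1`` slices guarantees that
    two sequences within the Hamming radius agree exactly on at least one
    slice, so only barcodes sharing a slice need explicit comparison.
    """
    n_parts = max_hamming + 1
    length = len(barcodes[0])
    bounds = np.linspace(0, length, n_parts + 1).astype(int)
    pairs: set[tuple[int, int]] = set()
    for p in range(n_parts):
        lo, hi = bounds[p], bounds[p + 1]
        buckets: dict[str, list[int]] = {}
        for i, bc in enumerate(barcodes):
            buckets.setdefault(bc[lo:hi], []).append(i)
        for members in buckets.values():
            if len(members) > 1:
                pairs.update(itertools.combinations(members, 2))
    return pairs


def collapse_sequencing_errors(
    table: pd.DataFrame,
    max_hamming: int = 2,
    min_ratio: float = 8.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Merge likely sequencing-error barcodes into their abundant parents.

    A barcode is merged into a neighbor within ``max_hamming`` when the
    neighbor is at least ``min_ratio`` times more abundant; counts are
    summed, so total reads are conserved.  If two candidate parents tie at
    the smallest distance the child is left unmerged and logged.  Merging
    iterates to a fixed point (children of children collapse upward).
    Returns the collapsed table and a merge report.
    """
    if table.empty:
        return table.copy(), []
    barcodes = list(table.index)
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have equal length")

    work = table.copy()
    report: list[dict] = []
    ambiguous_log: dict[str, dict] = {}
    while True:
        bcs = list(work.index)
        totals = work.sum(axis=1)
        pairs = _neighbor_candidates(bcs, max_hamming)
        # resolve children in ascending abundance so deep errors chain up
        parent_of: dict[str, str] = {}
        ambiguous: set[str] = set()
        cand: dict[str, list[tuple[int, str]]] = {}
        for i, j in pairs:
            a, b = bcs[i], bcs[j]
            d = _hamming(a, b)
            if d == 0 or d > max_hamming:
                continue
            child, parent = (a, b) if totals[a] < totals[b] else (b, a)
            if totals[child] == totals[parent]:
                continue
            if totals[parent] >= min_ratio * max(totals[child], 1):
                cand.setdefault(child, []).append((d, parent))
        for child, plist in cand.items():
            dmin = min(d for d, _ in plist)
            best = sorted({p for d, p in plist if d == dmin})
            if len(best) > 1:
                ambiguous.add(child)
                ambiguous_log[child] = {"barcode": child,
                                        "action": "ambiguous",
                                        "parents": best, "distance": dmin}
            else:
                parent_of[child] = best[0]
        if not parent_of:
            break
        # children that are themselves parents are deferred to next pass
        parent_of = {c: p for c, p in parent_of.items()
                     if c not in set(parent_of.values())}
        if not parent_of:
            break
        for child, parent in parent_of.items():
            work.loc[parent] += work.loc[child]
            report.append({"barcode": child, "action": "merged",
                           "parent": parent,
                           "distance": _hamming(child, parent)})
        work = work.drop(index=list(parent_of))
    report.extend(ambiguous_log[k] for k in sorted(ambiguous_log))
    return work, report
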