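"""Bookkeeping/summary code paths shared by the classifier tables and CLI.

These helpers are deliberately tiny and exact: every percentage the toolkit
prints flows through :func:`percent` so rounding is uniform everywhere.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

#: the canonical start-codon bucket used for usage summaries
CANONICAL_STARTS = frozenset({"ATG", "CTG", "GTG", "TTG"})

#: SEP length bins (aa) used in length-distribution summaries
LENGTH_BINS: tuple[tuple[str, int, int], ...] = (
    ("<50", 1, 49),
    ("50-75", 50, 75),
    ("76-100", 76, 100),
)

#: transcript class codes in reporting order
CLASS_CODES = ("u", "p", "x", "o", "c")


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage rounded to ``decimals``; 0.0 when the denominator is 0."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, decimals)


def start_codon_usage(counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-codon counts/percentages with a canonical/other bucket column."""
    total = sum(counts.values())
    rows = [
        {
            "codon": codon,
            "count": n,
            "pct": percent(n, total),
            "bucket": "canonical" if codon in CANONICAL_STARTS else "other",
        }
        for codon, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["codon", "count", "pct", "bucket"])


def canonical_start_share(counts: Mapping[str, int], decimals: int = 0) -> float:
    """Share of entries whose reported start codon is canonical."""
    total = sum(counts.values())
    canonical = sum(n for c, n in counts.items() if c in CANONICAL_STARTS)
    return percent(canonical, total, decimals)


def length_bin_table(lengths: Iterable[int]) -> pd.DataFrame:
    lengths = list(lengths)
    total = len(lengths)
    rows = []
    for label, lo, hi in LENGTH_BINS:
        n = sum(1 for x in lengths if lo <= x <= hi)
        rows.append({"bin": label, "count": n, "pct": percent(n, total)})
    return pd.DataFrame(rows, columns=["bin", "count", "pct"])


def coverage_bin_table(coverages: Iterable[float]) -> pd.DataFrame:
    """Coverage histogram over quartile bins of percent coverage."""
    coverages = list(coverages)
    total = len(coverages)
    edges = [(0.0, 25.0), (25.0, 50.0), (50.0, 75.0), (75.0, 100.0)]
    rows = []
    for lo, hi in edges:
        n = sum(1 for c in coverages if (lo < c <= hi) or (lo == 0.0 and c == 0.0))
        rows.append({"bin": f"{lo:g}-{hi:g}", "count": n, "pct": percent(n, total)})
    return pd.DataFrame(rows, columns=["bin", "count", "pct"])


def class_code_table(counts: Mapping[str, int]) -> pd.DataFrame:
    """Transcript class-code tally; counts must cover only known codes."""
    unknown = set(counts) - set(CLASS_CODES)
    if unknown:
        raise ValueError(f"unknown class codes: {sorted(unknown)}")
    rows = [{"class_code": c, "count": int(counts.get(c, 0))} for c in CLASS_CODES]
    df = pd.DataFrame(rows, columns=["class_code", "count"])
    df.attrs["total"] = int(df["count"].sum())
    return df


def total_candidates(per_method_counts: Mapping[str, int]) -> int:
    """Total novel candidates across discovery routes (simple conservation)."""
    if any(n < 0 for n in per_method_counts.values()):
        raise ValueError("counts must be non-negative")
    return int(sum(per_method_counts.values()))
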