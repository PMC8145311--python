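"""MS/MS peptidome hit-table filtering and downstream exports.

The tandem-MS stage identifies serum peptides per protein symbol and
counts, per comparison group, how many of the 8 sera per group were
positive for the protein and how many MS/MS "hits" (single-peptide
spectrum identifications, i.e. spectral counts) were accumulated. This
module models those hit tables, applies the differential filter (at
least a 2-fold difference in positive sera with a 3-sera floor, and a
1.5-fold or greater hit ratio after rounding to one decimal), exports
log2 hit ratios for pathway-analysis tools, and tallies the functional
phenotype annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .preprocess import ValidationError

#: Functional phenotype annotation codes used in the packaged hit tables.
PHENOTYPE_CODES = {
    1: "Alzheimer's disease/dementia/amyloidosis",
    2: "inflammation/neuroinflammation",
    3: "neurogenesis",
    4: "ion channels",
    5: "brain injury/CNS trauma/blood-brain barrier",
    6: "vasculature",
    7: "neuronal cell death",
}


@dataclass(frozen=True)
class HitTableEntry:
    """One protein symbol's per-group positive-sera and hit counts."""

    symbol: str
    sera_pos_A: int
    hits_A: int
    sera_pos_B: int
    hits_B: int
    annotations: frozenset[int] = frozenset()

    def __post_init__(self):
        for sera, hits, g in (
            (self.sera_pos_A, self.hits_A, "A"),
            (self.sera_pos_B, self.hits_B, "B"),
        ):
            if sera < 0 or hits < 0:
                raise ValidationError(f"{self.symbol}: negative counts in group {g}")
            if sera > 0 and hits == 0:
                raise ValidationError(
                    f"{self.symbol}: positive sera with zero hits in group {g}"
                )
        bad = set(self.annotations) - set(PHENOTYPE_CODES)
        if bad:
            raise ValidationError(f"{self.symbol}: unknown phenotype codes {sorted(bad)}")

    def swapped(self) -> "HitTableEntry":
        """The same entry with the two groups' columns exchanged."""
        return replace(
            self,
            sera_pos_A=self.sera_pos_B,
            hits_A=self.hits_B,
            sera_pos_B=self.sera_pos_A,
            hits_B=self.hits_A,
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the differential hit-table filter."""

    min_sera: int = 3
    sera_fold: float = 2.0
    hit_fold: float = 1.5
    n_per_group: int = 8

    def __post_init__(self):
        if min(self.min_sera, self.sera_fold, self.hit_fold, self.n_per_group) <= 0:
            raise ValidationError("all filter thresholds must be positive")


def _round1(x: float) -> float:
    """Round to one decimal, ties half-up (spreadsheet-style)."""
    return math.floor(x * 10.0 + 0.5) / 10.0


def _passes_one_direction(sera_hi, hits_hi, sera_lo, hits_lo, cfg: FilterConfig) -> bool:
    # a group with 0 positive sera / 0 hits is treated as infinitely exceeded
    if sera_hi < cfg.min_sera:
        return False
    if sera_lo > 0 and sera_hi / sera_lo < cfg.sera_fold:
        return False
    if hits_lo > 0 and _round1(hits_hi / hits_lo) < cfg.hit_fold:
        return False
    return True


def filter_entries(
    entries: list[HitTableEntry], cfg: FilterConfig = FilterConfig()
) -> tuple[list[HitTableEntry], list[HitTableEntry]]:
    """Split entries into (A-over-B, B-over-A) differential lists.

    An entry passes A-over-B iff its group-A positive-sera count reaches
    the ``min_sera`` floor, the sera ratio A/B reaches ``sera_fold``, and
    the hit ratio A/B — rounded to one decimal first — reaches
    ``hit_fold``; zero-count denominators pass their ratio test. The
    B-over-A test is the exact mirror. Entries passing neither are
    dropped; the filter is idempotent and symmetric under a group swap.
    """
    a_over_b, b_over_a = [], []
    for e in entries:
        if _passes_one_direction(e.sera_pos_A, e.hits_A, e.sera_pos_B, e.hits_B, cfg):
            a_over_b.append(e)
        if _passes_one_direction(e.sera_pos_B, e.hits_B, e.sera_pos_A, e.hits_A, cfg):
            b_over_a.append(e)
    return a_over_b, b_over_a


def log2_ratio_table(
    entries: list[HitTableEntry], pseudocount: float = 1.0
) -> dict[str, float]:
    """log2((hits_A + pc) / (hits_B + pc)) per symbol, finite for zero hits.

    This is the gene-expression-style export consumed by pathway-analysis
    tools; the pseudocount keeps zero-hit groups finite.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    return {
        e.symbol: math.log2((e.hits_A + pseudocount) / (e.hits_B + pseudocount))
        for e in entries
    }


def phenotype_tally(
    entries: list[HitTableEntry],
    categories: dict[int, str] = PHENOTYPE_CODES,
) -> pd.DataFrame:
    """Per-phenotype entry counts and integer percentages.

    Multi-annotated entries count in every category they carry;
    percentages are of the total entry count, rounded half-up.
    """
    total = len(entries)
    rows = []
    for code, name in sorted(categories.items()):
        count = sum(1 for e in entries if code in e.annotations)
        pct = int(math.floor(100.0 * count / total + 0.5)) if total else 0
        rows.append({"code": code, "phenotype": name, "count": count, "percent": pct})
    return pd.DataFrame(rows)


def load_hit_table(path_or_buf, label_A: str = "mildAD", label_B: str = "control") -> list[HitTableEntry]:
    """Read a hit-table TSV: symbol, sera/hits per group, annotation codes.

    Expected columns: ``symbol sera_mild hits_mild sera_control
    hits_control annotations`` (annotations comma-separated, optional).
    Group A maps to the mild-AD columns, group B to control.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"symbol": str, "annotations": str})
    entries = []
    for row in df.itertuples(index=False):
        ann = getattr(row, "annotations", None)
        if ann is None or (isinstance(ann, float) and np.isnan(ann)):
            codes = frozenset()
        else:
            codes = frozenset(int(c) for c in str(ann).split(",") if c.strip())
        entries.append(
            HitTableEntry(
                symbol=row.symbol,
                sera_pos_A=int(row.sera_mild),
                hits_A=int(row.hits_mild),
                sera_pos_B=int(row.sera_control),
                hits_B=int(row.hits_control),
                annotations=codes,
            )
        )
    symbols = [e.symbol for e in entries]
    if len(symbols) != len(set(symbols)):
        raise ValidationError("duplicate symbols in hit table")
    return entries


def packaged_hit_tables() -> tuple[list[HitTableEntry], list[HitTableEntry]]:
    """The two packaged differential hit tables (mild AD > control and
    control > mild AD), 154 entries in total, in unified A=mild-AD
    orientation."""
    base = resources.files("seroclass") / "data"
    with (base / "table3_mild_ad.tsv").open() as fh:
        t3 = load_hit_table(fh)
    with (base / "table4_control.tsv").open() as fh:
        t4 = load_hit_table(fh)
    return t3, t4
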