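"""Survey statistics over normalized torsion descriptors.

Two descriptors (the CF3 torsion C1–C2–C3–F3 and the ap-side amide torsion
X1''–N–C1–O1) concentrate around ±180° and therefore straddle the circular
seam.  Their central statistics are computed on a shifted branch: every
positive angle v is replaced by v − 360, giving a contiguous interval
(−360, 0], and the result is re-wrapped to (−180, +180] for reporting.  All
other descriptors live well inside the principal interval, so plain
arithmetic means/medians apply directly.

"As-printed" rounding follows the survey's own convention: medians quoted to
one decimal where one is printed, otherwise to the nearest degree, with
half-values rounded away from zero.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cif import Table1Row, TORSION_FIELDS
from .descriptors import (
    ConformerClass,
    TorsionSet,
    classify_conformer,
    normalize_to_R,
)

__all__ = [
    "DescriptorStats",
    "Histogram",
    "SummaryReport",
    "wrap_ap",
    "rewrap",
    "round_half_away",
    "descriptor_stats",
    "build_histogram",
    "tally_amide_forms",
    "summarize",
]

#: Windows for the windowed means, (lo, hi, lo_open, hi_open).
WINDOWS = {
    "theta1": (-30.0, 0.0, True, False),   # (−30, 0]
    "theta2": (0.0, 50.0, False, False),   # [0, +50]
    "tau_ome": (30.0, 80.0, False, False),  # [+30, +80]
}

#: Descriptors whose distributions straddle the ±180° seam.
AP_WRAPPED = {"tau_f3", "tau_ap"}


def wrap_ap(values: Iterable[float]) -> list[float]:
    """Shift positive angles down one turn: branch (−180, 180] → (−360, 0]."""
    return [v - 360.0 if v > 0 else v for v in values]


def rewrap(value: float) -> float:
    """Inverse of :func:`wrap_ap` for a single statistic."""
    return value + 360.0 if value <= -180.0 else value


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def _in_window(v: float, window) -> bool:
    lo, hi, lo_open, hi_open = window
    above = v > lo if lo_open else v >= lo
    below = v < hi if hi_open else v <= hi
    return above and below


@dataclass
class DescriptorStats:
    name: str
    n_total: int
    n_used: int
    mean_all: Optional[float]
    median_all: Optional[float]
    wrap_mode: str = "none"
    window: Optional[tuple] = None
    windowed_mean: Optional[float] = None
    n_in_window: Optional[int] = None
    excluded_rows: Optional[list[int]] = None

    @property
    def empty(self) -> bool:
        return self.n_used == 0

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "n_total": self.n_total,
            "n_used": self.n_used,
            "mean_all": self.mean_all,
            "median_all": self.median_all,
            "wrap_mode": self.wrap_mode,
        }
        if self.window is not None:
            lo, hi, lo_open, hi_open = self.window
            d["window"] = {
                "lo": lo, "hi": hi,
                "interval": f"{'(' if lo_open else '['}{lo:g}, {hi:g}{')' if hi_open else ']'}",
            }
            d["windowed_mean"] = self.windowed_mean
            d["n_in_window"] = self.n_in_window
            d["excluded_rows"] = self.excluded_rows
        return d


def descriptor_stats(
    values: Sequence[Optional[float]],
    name: str = "",
    window=None,
    wrap_mode: str = "none",
    row_ids: Optional[Sequence[int]] = None,
) -> DescriptorStats:
    """Mean/median (on the wrapped branch if requested) plus a windowed mean.

    ``values`` may contain ``None`` entries (absent atoms); they are dropped
    and only counted in ``n_total``.  The windowed mean averages the values
    inside ``window`` and records the identities of the excluded rows when
    ``row_ids`` is given.  Empty input yields an empty-stats marker.
    """
    if wrap_mode not in ("none", "ap_seam"):
        raise ValueError(f"unknown wrap_mode {wrap_mode!r}")
    n_total = len(values)
    if row_ids is None:
        row_ids = list(range(1, n_total + 1))
    pairs = [(r, v) for r, v in zip(row_ids, values) if v is not None]
    if not pairs:
        return DescriptorStats(name, n_total, 0, None, None, wrap_mode, window)
    used = [v for _, v in pairs]
    branch = wrap_ap(used) if wrap_mode == "ap_seam" else list(used)
    mean_all = rewrap(float(np.mean(branch)))
    median_all = rewrap(float(np.median(branch)))
    stats = DescriptorStats(name, n_total, len(used), mean_all, median_all,
                            wrap_mode, window)
    if window is not None:
        inside = [v for _, v in pairs if _in_window(v, window)]
        stats.n_in_window = len(inside)
        stats.windowed_mean = float(np.mean(inside)) if inside else None
        stats.excluded_rows = [r for r, v in pairs if not _in_window(v, window)]
    return stats


@dataclass
class Histogram:
    bin_width: float
    edges: list[float]          # n_bins + 1 ascending edges, multiples of w
    counts: list[int]
    wrap_mode: str = "none"

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "bins": [
                {"gt": self.edges[i], "le": self.edges[i + 1], "count": c}
                for i, c in enumerate(self.counts)
            ],
            "wrap_mode": self.wrap_mode,
        }


def build_histogram(
    values: Sequence[Optional[float]],
    bin_width: float = 10.0,
    wrap_mode: str = "none",
) -> Histogram:
    """10°-bin histogram with left-open, right-closed bins aligned to 0.

    A value of exactly 0 falls in the (−10, 0] bin.  For seam-straddling
    descriptors the histogram is built on the shifted (−360, 0] branch.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    used = [v for v in values if v is not None]
    branch = wrap_ap(used) if wrap_mode == "ap_seam" else used
    if not branch:
        return Histogram(bin_width, [-bin_width, 0.0], [0], wrap_mode)
    # bin index k holds (k*w, (k+1)*w]
    idx = [math.ceil(v / bin_width) - 1 for v in branch]
    lo, hi = min(idx), max(idx)
    counts = [0] * (hi - lo + 1)
    for k in idx:
        counts[k - lo] += 1
    edges = [k * bin_width for k in range(lo, hi + 2)]
    return Histogram(bin_width, edges, counts, wrap_mode)


def tally_amide_forms(items: Iterable[tuple[str, str]]) -> dict[str, tuple[int, int, int]]:
    """Z/E/indeterminate counts per amide group.

    ``items`` are (group, form) pairs; the survey groups its tally into the
    tertiary amides (from secondary amines), the secondary amides (from
    primary amines), and everything else.
    """
    groups: dict[str, Counter] = {}
    for group, form in items:
        groups.setdefault(group, Counter())[form] += 1
    return {
        g: (c.get("Z", 0), c.get("E", 0), c.get("indeterminate", 0))
        for g, c in groups.items()
    }


def _arity_group(amine_class: str) -> str:
    if amine_class == "primary_amine":
        return "secondary"
    if amine_class == "secondary_amine":
        return "tertiary"
    return "other"


@dataclass
class SummaryReport:
    n_moieties: int
    n_structures: int
    amine_class_counts: dict[str, int]
    stats: dict[str, DescriptorStats]
    histograms: dict[str, Histogram]
    amide_form_tally: dict[str, tuple[int, int, int]]
    conformers: dict[int, ConformerClass]
    mosher_rows: list[int]
    anti_rows: list[int]

    def to_dict(self) -> dict:
        return {
            "n_moieties": self.n_moieties,
            "n_structures": self.n_structures,
            "amine_class_counts": dict(self.amine_class_counts),
            "descriptors": {k: v.to_dict() for k, v in self.stats.items()},
            "histograms": {k: v.to_dict() for k, v in self.histograms.items()},
            "amide_form_tally": {
                g: {"Z": z, "E": e, "indeterminate": i}
                for g, (z, e, i) in self.amide_form_tally.items()
            },
            "mosher_rows": self.mosher_rows,
            "anti_rows": self.anti_rows,
            "as_printed": self.as_printed(),
        }

    def as_printed(self) -> dict:
        """The headline panel, rounded the way the survey prints it."""
        s = self.stats
        panel = {
            "theta1_median": round_half_away(s["theta1"].median_all, 1),
            "theta1_windowed_mean": round_half_away(s["theta1"].windowed_mean),
            "theta1_n_in_window": s["theta1"].n_in_window,
            "tau_f3_median": round_half_away(s["tau_f3"].median_all),
            "tau_sp_mean": round_half_away(s["tau_sp"].mean_all),
            "tau_sp_median": round_half_away(s["tau_sp"].median_all, 1),
            "tau_ap_median": round_half_away(s["tau_ap"].median_all),
            "tau_h_mean": round_half_away(s["tau_h"].mean_all),
            "tau_h_median": round_half_away(s["tau_h"].median_all),
            "theta2_windowed_mean": round_half_away(s["theta2"].windowed_mean),
            "theta2_n_in_window": s["theta2"].n_in_window,
            "theta2_median": round_half_away(s["theta2"].median_all),
            "tau_ome_windowed_mean": round_half_away(s["tau_ome"].windowed_mean),
            "tau_ome_n_in_window": s["tau_ome"].n_in_window,
            "tau_ome_median": round_half_away(s["tau_ome"].median_all),
        }
        return panel


def summarize(rows: Sequence[Table1Row],
              include_row58_tau_sp: bool = True) -> SummaryReport:
    """Full survey report over (a copy of) the 58-row table.

    Rows are mirror-normalized to the R-acid frame first; the H1'–C1'–N–C1
    statistics are restricted to the Mosher-type subset (secondary amides
    whose sp substituent is a secondary alkyl group).  ``include_row58_tau_sp``
    keeps or drops the one row whose C1' column stores an S–N–C1–O1 angle
    (a sulfonamide nitrogen substituent) from the amide-planarity statistics.
    """
    normalized: dict[int, TorsionSet] = {}
    conformers: dict[int, ConformerClass] = {}
    for row in rows:
        ts = normalize_to_R(TorsionSet.from_values(row.torsions(), row.chirality))
        normalized[row.row_no] = ts
        conformers[row.row_no] = classify_conformer(
            ts, row.rsp_class, row.rap_class, row.amide_arity)

    row_ids = [r.row_no for r in rows]

    def column(name: str) -> list[Optional[float]]:
        return [getattr(normalized[r.row_no], name) for r in rows]

    stats: dict[str, DescriptorStats] = {}
    histograms: dict[str, Histogram] = {}
    mosher_rows = [r.row_no for r in rows if conformers[r.row_no].mosher_type]
    for name in TORSION_FIELDS:
        values = column(name)
        ids = list(row_ids)
        if name == "tau_h":
            values = [v for r, v in zip(rows, values)
                      if r.row_no in mosher_rows]
            ids = list(mosher_rows)
        if name == "tau_sp" and not include_row58_tau_sp:
            values = [v for r, v in zip(rows, values)
                      if "j" not in r.footnote_flags]
            ids = [r.row_no for r in rows if "j" not in r.footnote_flags]
        wrap_mode = "ap_seam" if name in AP_WRAPPED else "none"
        stats[name] = descriptor_stats(
            values, name=name, window=WINDOWS.get(name),
            wrap_mode=wrap_mode, row_ids=ids)
        histograms[name] = build_histogram(values, wrap_mode=wrap_mode)

    tally = tally_amide_forms(
        (_arity_group(r.amine_class), conformers[r.row_no].amide_form)
        for r in rows)
    anti_rows = [r.row_no for r in rows
                 if conformers[r.row_no].carbonyl_methoxy == "anti"]
    return SummaryReport(
        n_moieties=len(rows),
        n_structures=len({r.ccdc for r in rows}),
        amine_class_counts=dict(Counter(r.amine_class for r in rows)),
        stats=stats,
        histograms=histograms,
        amide_form_tally=tally,
        conformers=conformers,
        mosher_rows=mosher_rows,
        anti_rows=anti_rows,
    )
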