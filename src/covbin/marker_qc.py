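"""Bin completeness and contamination from single-copy marker hits.

A single-copy marker gene occurs exactly once in nearly every genome of
a clade, so the fraction of a marker set found in a bin estimates how
complete the recovered genome is, and excess copies signal that the bin
mixes more than one population. Marker detection itself (gene calling,
HMM search) happens upstream; this module only consumes a hit table of
(contig_id, marker_id) rows plus the marker-set list.

Contamination counts *excess copies* — sum over markers of
max(0, copies - 1) as a percentage of the set size — rather than merely
the fraction of multi-copy markers, so a marker present five times in a
bin contributes four points per hundred markers, not one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class BinQuality:
    completeness: float  # percent of the marker set present at least once
    contamination: float  # percent of excess marker copies


def bin_quality(marker_hits, marker_set) -> BinQuality:
    """Score one bin's marker hits against a marker set.

    *marker_hits*: iterable of (contig_id, marker_id) rows for contigs in
    the bin. Hits whose marker id is outside the set are ignored with no
    error (the set defines the universe). Empty marker set is an error.
    """
    markers = list(dict.fromkeys(marker_set))
    if not markers:
        raise ValueError("marker set is empty")
    m = len(markers)
    universe = set(markers)
    copies = Counter(mid for _cid, mid in marker_hits if mid in universe)
    completeness = 100.0 * sum(1 for c in copies.values() if c >= 1) / m
    contamination = 100.0 * sum(c - 1 for c in copies.values() if c > 1) / m
    return BinQuality(completeness=completeness, contamination=contamination)


def read_marker_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a contig_id<TAB>marker_id hit table."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        contig_id, marker_id = line.split("\t")[:2]
        rows.append((contig_id, marker_id))
    return rows


def read_marker_set(path: str | Path) -> list[str]:
    """Read a marker set: one marker id per line."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
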