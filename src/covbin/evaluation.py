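"""Binning-accuracy evaluation against verified (ground-truth) bins.

Each contig carries a *verified bin* label — the population genome it
truly came from. Strain groups whose members cannot be told apart at the
contig level (chimeric assembly across near-identical genomes) are first
collapsed into single populations. Predicted bins are then coupled to
verified bins by an iterative plurality-matching procedure that ends
with an injective coupling, and every contig is classified as binned
correctly, binned incorrectly or unassigned. Accuracy is reported under
two weightings: total number of contigs (TNC) and total assembled bases
(TAB).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CLASSES = ("correct", "incorrect", "unassigned")


def make_truth_table(contig_ids, verified_bin_ids, lengths) -> pd.DataFrame:
    """Assemble a truth table: one row per contig, positive lengths."""
    df = pd.DataFrame(
        {
            "contig_id": list(contig_ids),
            "verified_bin_id": [str(v) for v in verified_bin_ids],
            "length": list(lengths),
        }
    )
    if df["contig_id"].duplicated().any():
        raise ValueError("duplicate contig ids in truth table")
    if (df["length"] <= 0).any():
        raise ValueError("truth lengths must be positive")
    return df


def read_truth_table(path: str | Path, lengths: dict) -> pd.DataFrame:
    """Read contig_id<TAB>verified_bin_id rows; lengths come from the store."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cid, vid = line.split("\t")[:2]
        rows.append((cid, vid, lengths[cid]))
    return make_truth_table(*zip(*rows))


def read_strain_groups(path: str | Path) -> list[set]:
    """Read strain groups: one comma-separated group of verified ids per line."""
    groups = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        groups.append({v.strip() for v in line.split(",") if v.strip()})
    return groups


def collapse_verified_bins(truth: pd.DataFrame, groups) -> pd.DataFrame:
    """Collapse indistinguishable-strain groups into single populations.

    All verified ids inside a group are rewritten to the group's
    lexicographically smallest id; groups must be disjoint and their
    members present in the truth table.
    """
    groups = [set(map(str, g)) for g in groups]
    seen: set = set()
    for g in groups:
        if g & seen:
            raise ValueError(f"overlapping strain groups: {sorted(g & seen)}")
        seen |= g
    present = set(truth["verified_bin_id"])
    rename = {}
    for g in groups:
        missing = g - present
        if missing:
            raise ValueError(f"strain-group members absent from truth: {sorted(missing)}")
        target = min(g)
        for vid in g:
            rename[vid] = target
    out = truth.copy()
    out["verified_bin_id"] = out["verified_bin_id"].map(lambda v: rename.get(v, v))
    return out


def _membership(predicted) -> dict:
    """Accept a BinSet or a {bin_id: contig-id iterable} mapping."""
    if hasattr(predicted, "bins"):
        return {bid: set(b.members) for bid, b in predicted.bins.items()}
    return {bid: set(members) for bid, members in predicted.items()}


def match_bins(predicted, truth: pd.DataFrame) -> dict:
    """Couple each predicted bin to exactly one verified bin, injectively.

    Every predicted bin first proposes the verified bin holding the
    plurality of its contigs (ties broken by larger cumulative member
    length in that verified bin, then lexicographic verified id). When
    several bins propose the same verified bin they are ranked by the
    cumulative length of their contigs belonging to it (descending; ties
    by lexicographic predicted id) and only the top-ranked keeps it;
    losers re-propose among verified bins not yet taken, iterating until
    the coupling is injective. A bin that exhausts its candidates is
    coupled to a fresh unmatched placeholder.
    """
    bins = _membership(predicted)
    vid_of = dict(zip(truth["contig_id"], truth["verified_bin_id"]))
    len_of = dict(zip(truth["contig_id"], truth["length"]))

    missing = sorted(
        {c for members in bins.values() for c in members if c not in vid_of}
    )
    if missing:
        raise KeyError(f"contigs missing from truth table: {missing[:10]}")

    # per predicted bin: candidate verified bins ranked by
    # (contig count desc, cumulative length desc, verified id asc)
    candidates: dict = {}
    weight: dict = {}  # (pid, vid) -> cumulative length, for conflict ranking
    for pid, members in bins.items():
        tally: dict = {}
        for c in members:
            vid = vid_of[c]
            cnt, bp = tally.get(vid, (0, 0))
            tally[vid] = (cnt + 1, bp + len_of[c])
        order = sorted(tally, key=lambda v: (-tally[v][0], -tally[v][1], v))
        candidates[pid] = order
        for vid, (_cnt, bp) in tally.items():
            weight[(pid, vid)] = bp

    coupling: dict = {}
    taken: set = set()
    remaining = sorted(bins, key=str)
    while remaining:
        proposals: dict = {}
        next_remaining = []
        for pid in remaining:
            cand = [v for v in candidates[pid] if v not in taken]
            if not cand:
                coupling[pid] = f"unmatched:{pid}"
                continue
            proposals.setdefault(cand[0], []).append(pid)
        for vid in sorted(proposals):
            ranked = sorted(proposals[vid], key=lambda p: (-weight[(p, vid)], str(p)))
            winner = ranked[0]
            coupling[winner] = vid
            taken.add(vid)
            next_remaining.extend(ranked[1:])
        remaining = sorted(next_remaining, key=str)
    return coupling


@dataclass
class EvaluationReport:
    """Correct / incorrect / unassigned under contig (TNC) and base (TAB) weights."""

    counts: dict
    bases: dict
    tnc: dict  # percent of total contigs per class
    tab: dict  # percent of total bases per class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contigs": [self.counts[c] for c in CLASSES],
                "TNC_percent": [self.tnc[c] for c in CLASSES],
                "bases": [self.bases[c] for c in CLASSES],
                "TAB_percent": [self.tab[c] for c in CLASSES],
            },
            index=list(CLASSES),
        )

    def summary(self) -> str:
        lines = ["class       contigs   TNC%      bases        TAB%"]
        for c in CLASSES:
            lines.append(
                f"{c:<11}{self.counts[c]:>8}{self.tnc[c]:>8.1f}"
                f"{self.bases[c]:>13}{self.tab[c]:>8.1f}"
            )
        return "\n".join(lines)


def score_binning(predicted, truth: pd.DataFrame, coupling: dict | None = None) -> EvaluationReport:
    """Classify every truth contig and report TNC/TAB percentages.

    A binned contig is correct when its verified bin equals the verified
    bin its predicted bin is coupled with; other binned contigs are
    incorrect; contigs in no predicted bin are unassigned.
    """
    bins = _membership(predicted)
    if coupling is None:
        coupling = match_bins(bins, truth)
    bin_of: dict = {}
    for pid, members in bins.items():
        for c in members:
            bin_of[c] = pid

    counts = dict.fromkeys(CLASSES, 0)
    bases = dict.fromkeys(CLASSES, 0)
    for cid, vid, length in truth[["contig_id", "verified_bin_id", "length"]].itertuples(
        index=False
    ):
        pid = bin_of.get(cid)
        if pid is None:
            cls = "unassigned"
        elif coupling[pid] == vid:
            cls = "correct"
        else:
            cls = "incorrect"
        counts[cls] += 1
        bases[cls] += int(length)

    total_n = sum(counts.values())
    total_bp = sum(bases.values())
    tnc = {c: 100.0 * counts[c] / total_n for c in CLASSES}
    tab = {c: 100.0 * bases[c] / total_bp for c in CLASSES}
    return EvaluationReport(counts=counts, bases=bases, tnc=tnc, tab=tab)
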