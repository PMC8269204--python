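"""Conserved-region discovery by sliding 3-mer Shannon entropy.

A window of three alignment columns is summarized by the Shannon entropy (in
bits) of the distinct tripeptides observed across rows; rows gapped anywhere
in the window are excluded and reported through the window's gap fraction,
rather than treated as a 21st symbol, so gap-rich regions do not masquerade
as conserved.  Runs of low-entropy windows form candidate functional regions,
which are then labelled with the ten halogenase functional sites (FAD1-4,
catalytic Lys, halide, Trp1-4) by matching degenerate anchor patterns against
the rows under each region.

Anchor patterns are shipped as data (an editable TSV), not code.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

from .seqio import MultipleAlignment

#: Canonical functional-site labels, in model order.
SITE_LABELS = (
    "FAD1", "FAD2", "Trp1", "Trp2", "Trp3", "K", "FAD3", "FAD4", "halide", "Trp4",
)

WINDOW_WIDTH = 3


class AmbiguityError(ValueError):
    """Two regions score equally well for the same functional site."""


@dataclass
class EntropyTrack:
    """Per-window entropies over an alignment; window w covers columns w..w+2."""

    window_entropies: list[float]  # bits; NaN where every row is gapped
    gap_fractions: list[float]
    n_cols: int

    def __len__(self) -> int:
        return len(self.window_entropies)


@dataclass
class ConservedRegion:
    start_col: int  # 1-based inclusive
    end_col: int
    mean_entropy: float
    gap_fraction: float
    label: str = "unlabeled"

    @property
    def span(self) -> int:
        return self.end_col - self.start_col + 1


def window_entropy(msa: MultipleAlignment, start_col: int) -> tuple[float, float]:
    """Entropy (bits) of the 3-mers in columns ``start_col..start_col+2``.

    Returns ``(entropy, gap_fraction)``; rows with any gap in the window are
    excluded and counted in the gap fraction.  If every row is gapped the
    entropy is NaN (flagged missing).
    """
    if not 1 <= start_col <= msa.n_cols - WINDOW_WIDTH + 1:
        raise IndexError(
            f"window start {start_col} outside 1..{msa.n_cols - WINDOW_WIDTH + 1}"
        )
    kmers = []
    for row in msa.rows:
        w = row[start_col - 1 : start_col - 1 + WINDOW_WIDTH]
        if "-" not in w:
            kmers.append(w)
    gap_fraction = 1.0 - len(kmers) / msa.n_rows
    if not kmers:
        return float("nan"), 1.0
    counts: dict[str, int] = {}
    for k in kmers:
        counts[k] = counts.get(k, 0) + 1
    n = len(kmers)
    entropy = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return entropy + 0.0, gap_fraction  # +0.0 normalizes -0.0


def entropy_track(msa: MultipleAlignment) -> EntropyTrack:
    ents, gaps = [], []
    for start in range(1, msa.n_cols - WINDOW_WIDTH + 2):
        e, g = window_entropy(msa, start)
        ents.append(e)
        gaps.append(g)
    return EntropyTrack(ents, gaps, msa.n_cols)


def find_conserved_regions(
    track: EntropyTrack,
    tau: float = 1.0,
    max_gap_fraction: float = 0.5,
    min_len: int = 3,
) -> list[ConservedRegion]:
    """Maximal runs of windows with entropy <= tau and tolerable gap fraction.

    Consecutive qualifying windows merge into one region spanning the union
    of their columns; regions spanning fewer than ``min_len`` columns are
    discarded.
    """
    regions: list[ConservedRegion] = []
    run: list[int] = []  # window start columns (1-based)

    def flush() -> None:
        if not run:
            return
        start, end = run[0], run[-1] + WINDOW_WIDTH - 1
        if end - start + 1 >= min_len:
            ents = [track.window_entropies[w - 1] for w in run]
            gaps = [track.gap_fractions[w - 1] for w in run]
            regions.append(ConservedRegion(
                start_col=start, end_col=end,
                mean_entropy=sum(ents) / len(ents),
                gap_fraction=sum(gaps) / len(gaps),
            ))
        run.clear()

    for w, (e, g) in enumerate(zip(track.window_entropies, track.gap_fractions), start=1):
        if not math.isnan(e) and e <= tau and g <= max_gap_fraction:
            if run and w != run[-1] + 1:
                flush()
            run.append(w)
        else:
            flush()
    flush()
    return regions


def column_conservation(msa: MultipleAlignment, col: int) -> list[tuple[str, float]]:
    """Residue percentages among non-gap rows of a column, sorted descending."""
    column = msa.column(col)
    residues = [c for c in column if c != "-"]
    if not residues:
        return []
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    out = [(r, 100.0 * n / len(residues)) for r, n in counts.items()]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


# --- anchor tables -----------------------------------------------------

def _compile(pattern: str) -> re.Pattern:
    """Degenerate anchor pattern -> regex ('x' is any residue)."""
    return re.compile(pattern.replace("x", "."))


def load_anchor_table(path=None) -> dict[str, list[re.Pattern]]:
    """Load site anchor patterns from a TSV (site <TAB> pattern per line).

    Defaults to the bundled table derived from the characterized-halogenase
    motif catalogue.
    """
    if path is None:
        text = resources.files("halomotif.data").joinpath("anchors.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    anchors: dict[str, list[re.Pattern]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        site, pattern = line.split("\t")[:2]
        anchors.setdefault(site, []).append(_compile(pattern))
    return anchors


def _region_match_fraction(
    region: ConservedRegion, msa: MultipleAlignment, patterns: list[re.Pattern]
) -> float:
    """Fraction of non-gap rows whose region substring matches any pattern."""
    matched = total = 0
    for row in msa.rows:
        sub = row[region.start_col - 1 : region.end_col].replace("-", "")
        if not sub:
            continue
        total += 1
        if any(p.search(sub) for p in patterns):
            matched += 1
    return matched / total if total else 0.0


def label_sites(
    regions: list[ConservedRegion],
    msa: MultipleAlignment,
    anchors: dict[str, list[re.Pattern]] | None = None,
    min_match_fraction: float = 0.5,
) -> list[ConservedRegion]:
    """Assign functional-site labels to conserved regions via anchor motifs.

    A region receives a site label when at least ``min_match_fraction`` of
    non-gap rows match one of the site's patterns within the region's columns;
    each site labels at most one region (the best-scoring one).  Equal best
    scores for one site raise :class:`AmbiguityError`.
    """
    if anchors is None:
        anchors = load_anchor_table()
    labeled = [ConservedRegion(r.start_col, r.end_col, r.mean_entropy,
                               r.gap_fraction) for r in regions]
    for site, patterns in anchors.items():
        scores = [
            _region_match_fraction(r, msa, patterns) if r.label == "unlabeled" else 0.0
            for r in labeled
        ]
        best = max(scores, default=0.0)
        if best < min_match_fraction:
            continue
        winners = [i for i, s in enumerate(scores) if s == best]
        if len(winners) > 1:
            spans = [(labeled[i].start_col, labeled[i].end_col) for i in winners]
            raise AmbiguityError(f"site {site}: regions {spans} tie at match fraction {best:.2f}")
        labeled[winners[0]].label = site
    return labeled
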