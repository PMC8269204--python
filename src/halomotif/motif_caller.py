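"""Group and regioselectivity calls from tryptophan-binding motifs.

Characterized flavin-dependent halogenases fall into five clusters — A1
(7-Trp), A2 (6-Trp), B2 (6-Trp), B1 (5-Trp) and C (non-tryptophan,
indole-type) — and the residue patterns of four tryptophan-binding regions
(Trp1-4) encode the cluster.  The caller extracts those regions from a query
via its profile alignment and applies a weighted rule vote:

* R1 (weight 2): Trp4 absent -> C; long (19-residue) form -> group A;
  short (9-residue) form -> group B.  Trp4 is the substrate-scope
  discriminator: halogenases lacking it do not act on free tryptophan.
* R2 (weight 2): within A, the residue preceding the C-terminal YY of Trp4
  (N -> A1, S -> A2); within B, Trp4 positions 5-6 (FE -> B1, LP -> B2).
* R3 (weight 1): Trp1 tail (IP -> A1, VP -> A2, ...STV -> B1, ...SDI -> B2).
* R4 (weight 1): Trp2 second residue (L/S -> A1, P -> {A2,B1,B2}) and fifth
  residue (R -> B1, Q -> B2).
* R5 (weight 1): Trp3 presence -> group B; QxxQ spacing -> B1, QxxxQ -> B2.

Because Trp1/Trp2 motifs occur in every group — including the non-Trp group
C — their sub-patterns carry no information about family membership, only
about regiochemistry within the tryptophan-halogenase family.  The
refinement rules R3-R5 therefore vote only when Trp4 is present; when it is
absent, R1 alone decides (group C).  Double weight on the Trp4-derived rules
reflects the mutagenesis evidence that Trp4 swaps dominate regioselectivity
switching while Trp1/Trp2 swaps alone do not alter it.

The fixed group->regioselectivity map is A1->7, A2->6, B1->5, B2->6,
C->non-Trp.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .motif_discovery import ConservedRegion
from .profile_hmm import ProfileHMM, viterbi_align
from .seqio import MultipleAlignment, SequenceRecord

GROUPS = ("A1", "A2", "B1", "B2", "C")
REGIOSELECTIVITY = {"A1": "7", "A2": "6", "B1": "5", "B2": "6", "C": "non-Trp"}

MOTIF_SITES = ("Trp1", "Trp2", "Trp3", "Trp4")


class ExtractionError(ValueError):
    """Query does not align to any profile well enough to extract motifs."""


@dataclass(frozen=True)
class Motif:
    text: str
    position: int | None = None  # 1-based on the ungapped query, when known


@dataclass
class MotifSet:
    """Extracted functional-site strings for one query (absent = None)."""

    query_id: str
    sites: dict[str, Motif] = field(default_factory=dict)

    def get(self, site: str) -> str | None:
        m = self.sites.get(site)
        return m.text if m else None

    @property
    def trp1(self) -> str | None:
        return self.get("Trp1")

    @property
    def trp2(self) -> str | None:
        return self.get("Trp2")

    @property
    def trp3(self) -> str | None:
        return self.get("Trp3")

    @property
    def trp4(self) -> str | None:
        return self.get("Trp4")


def motifset(query_id: str, trp1=None, trp2=None, trp3=None, trp4=None) -> MotifSet:
    """Convenience constructor from bare motif strings."""
    sites = {}
    for name, text in (("Trp1", trp1), ("Trp2", trp2), ("Trp3", trp3), ("Trp4", trp4)):
        if text:
            sites[name] = Motif(text)
    return MotifSet(query_id, sites)


@dataclass(frozen=True)
class Vote:
    rule: str
    groups: tuple[str, ...]
    weight: float
    evidence: str


@dataclass
class CallResult:
    query_id: str
    group: str  # one of GROUPS or "ambiguous"
    regioselectivity: str  # "7" | "6" | "5" | "non-Trp" | "NA"
    votes: list[Vote]
    confidence: float

    def tally(self) -> dict[str, float]:
        scores = {g: 0.0 for g in GROUPS}
        for v in self.votes:
            for g in v.groups:
                if g in scores:
                    scores[g] += v.weight
        return scores

    def margin(self, group_a: str, group_b: str) -> float:
        """Vote score of ``group_a`` minus that of ``group_b``."""
        t = self.tally()
        return t[group_a] - t[group_b]


# --- motif extraction ----------------------------------------------------

def site_columns_from_regions(
    regions: list[ConservedRegion],
    msa: MultipleAlignment,
    anchors: dict[str, list[re.Pattern]],
    model: ProfileHMM,
) -> dict[str, list[int]]:
    """Map labelled conserved regions to exact match-state column sets.

    Entropy-derived region boundaries can overshoot a motif by a column or
    two, so each labelled region is trimmed to the span where the site's
    anchor pattern matches the region's majority-consensus string.  Returns,
    per site, the 1-based match-state indices of the model.
    """
    col_to_node = {int(c): l + 1 for l, c in enumerate(model.column_map)}
    out: dict[str, list[int]] = {}
    for region in regions:
        if region.label == "unlabeled" or region.label not in anchors:
            continue
        consensus = _region_consensus(msa, region)
        span = None
        for pattern in anchors[region.label]:
            m = pattern.search(consensus)
            if m:
                span = (region.start_col + m.start(), region.start_col + m.end() - 1)
                break
        if span is None:  # fall back to the full region
            span = (region.start_col, region.end_col)
        nodes = [col_to_node[c] for c in range(span[0], span[1] + 1) if c in col_to_node]
        if nodes:
            out[region.label] = nodes
    return out


def _region_consensus(msa: MultipleAlignment, region: ConservedRegion) -> str:
    chars = []
    for col in range(region.start_col, region.end_col + 1):
        column = [c for c in msa.column(col) if c != "-"]
        if not column:
            chars.append("X")
            continue
        counts: dict[str, int] = {}
        for c in column:
            counts[c] = counts.get(c, 0) + 1
        chars.append(max(sorted(counts), key=lambda c: counts[c]))
    return "".join(chars)


def extract_motifs(
    query: SequenceRecord,
    model: ProfileHMM,
    site_columns: dict[str, list[int]],
    min_coverage: float = 0.3,
    min_site_fraction: float = 0.5,
) -> MotifSet:
    """Extract site substrings from a query via its Viterbi alignment.

    A site is absent when the query has a deletion across more than
    ``1 - min_site_fraction`` of the site's columns.
    """
    aln = viterbi_align(model, query)
    if aln.model_coverage < min_coverage:
        raise ExtractionError(
            f"query {query.id!r} is not FDH-like: model coverage "
            f"{aln.model_coverage:.3f} < {min_coverage}"
        )
    sites: dict[str, Motif] = {}
    for site, nodes in site_columns.items():
        mapped = [aln.match_map[n] for n in nodes if n in aln.match_map]
        if not nodes or len(mapped) / len(nodes) <= min_site_fraction:
            continue
        start, end = min(mapped), max(mapped)
        sites[site] = Motif(query.residues[start - 1 : end], position=start)
    return MotifSet(query.id, sites)


# --- the grammar ---------------------------------------------------------

_A_FORM_MIN_LEN = 14  # 19-residue group-A form vs 9-residue group-B form


def _collect_votes(m: MotifSet) -> list[Vote]:
    votes: list[Vote] = []
    if not m.sites:
        return votes  # no motifs at all: no evidence, not a group-C call
    trp4 = m.trp4
    if trp4 is None:
        votes.append(Vote("R1", ("C",), 2.0, "Trp4 absent"))
        return votes  # refinement rules are uninformative outside the Trp family

    a_form = len(trp4) >= _A_FORM_MIN_LEN
    votes.append(Vote("R1", ("A1", "A2") if a_form else ("B1", "B2"), 2.0,
                      f"Trp4 {'long' if a_form else 'short'} form ({len(trp4)} aa)"))

    if a_form:
        if len(trp4) >= 4 and trp4.endswith("YY"):
            r = trp4[-3]
            if r == "N":
                votes.append(Vote("R2", ("A1",), 2.0, f"Trp4 ...{trp4[-4:]}"))
            elif r == "S":
                votes.append(Vote("R2", ("A2",), 2.0, f"Trp4 ...{trp4[-4:]}"))
    elif len(trp4) >= 6:
        core = trp4[4:6]
        if core == "FE":
            votes.append(Vote("R2", ("B1",), 2.0, f"Trp4[5:6]={core}"))
        elif core == "LP":
            votes.append(Vote("R2", ("B2",), 2.0, f"Trp4[5:6]={core}"))

    trp1 = m.trp1
    if trp1 and len(trp1) >= 4:
        tail = trp1[2:4]
        if tail == "IP":
            votes.append(Vote("R3", ("A1",), 1.0, f"Trp1 {trp1} (IP)"))
        elif tail == "VP":
            votes.append(Vote("R3", ("A2",), 1.0, f"Trp1 {trp1} (VP)"))
        elif trp1.endswith("STV"):
            votes.append(Vote("R3", ("B1",), 1.0, f"Trp1 {trp1} (STV)"))
        elif trp1.endswith("SDI"):
            votes.append(Vote("R3", ("B2",), 1.0, f"Trp1 {trp1} (SDI)"))

    trp2 = m.trp2
    if trp2 and len(trp2) >= 2:
        second = trp2[1]
        if second in "LS":
            votes.append(Vote("R4", ("A1",), 1.0, f"Trp2 {trp2} (2nd={second})"))
        elif second == "P":
            votes.append(Vote("R4", ("A2", "B1", "B2"), 1.0, f"Trp2 {trp2} (2nd=P)"))
        if len(trp2) >= 5:
            fifth = trp2[4]
            if fifth == "R":
                votes.append(Vote("R4", ("B1",), 1.0, f"Trp2 {trp2} (5th=R)"))
            elif fifth == "Q":
                votes.append(Vote("R4", ("B2",), 1.0, f"Trp2 {trp2} (5th=Q)"))

    trp3 = m.trp3
    if trp3:
        votes.append(Vote("R5", ("B1", "B2"), 1.0, f"Trp3 {trp3} present"))
        b2_elsewhere = (trp1 or "").endswith("SDI") or (trp4[4:6] == "LP" if len(trp4) >= 6 else False)
        if re.fullmatch("Q..Q", trp3):
            # a 4-residue spacing normally reads B1; known B2 members carry it
            # too, so the spacing sub-rule abstains when Trp1/Trp4 say B2
            if not b2_elsewhere:
                votes.append(Vote("R5", ("B1",), 1.0, f"Trp3 {trp3} QxxQ"))
        elif re.fullmatch("Q...Q", trp3):
            votes.append(Vote("R5", ("B2",), 1.0, f"Trp3 {trp3} QxxxQ"))
    return votes


def classify_by_motifs(motifs: MotifSet) -> CallResult:
    """Weighted rule vote over the Trp1-4 motif grammar.

    Returns the argmax group with its fixed regioselectivity; vote ties (or
    no votes at all) yield an ``ambiguous`` call to be arbitrated against
    nearest-neighbour evidence by :func:`consensus_call`.
    """
    votes = _collect_votes(motifs)
    scores = {g: 0.0 for g in GROUPS}
    for v in votes:
        for g in v.groups:
            scores[g] += v.weight
    best = max(scores.values())
    winners = [g for g in GROUPS if scores[g] == best]
    if best == 0.0 or len(winners) > 1:
        return CallResult(motifs.query_id, "ambiguous", "NA", votes, 0.0)
    group = winners[0]
    total = sum(v.weight for v in votes)
    agreeing = sum(v.weight for v in votes if group in v.groups)
    return CallResult(motifs.query_id, group, REGIOSELECTIVITY[group], votes,
                      agreeing / total)


def consensus_call(
    motif_call: CallResult,
    knn_label: str | None,
    knn_distance: float | None,
) -> CallResult:
    """Arbitrate the motif-grammar call against nearest-neighbour evidence.

    A decided motif call wins and the neighbour's (dis)agreement is recorded;
    an ambiguous motif call adopts the neighbour label with confidence
    ``0.5 * (motif confidence + 1 / (1 + distance))``.
    """
    votes = list(motif_call.votes)
    if knn_label is None:
        return motif_call
    if motif_call.group != "ambiguous":
        agree = "agrees" if knn_label == motif_call.group else "disagrees"
        votes.append(Vote("knn", (knn_label,), 0.0,
                          f"1-NN {knn_label} ({agree}), distance {knn_distance:.4g}"))
        return CallResult(motif_call.query_id, motif_call.group,
                          motif_call.regioselectivity, votes, motif_call.confidence)
    votes.append(Vote("knn", (knn_label,), 0.0,
                      f"1-NN fallback, distance {knn_distance:.4g}"))
    confidence = 0.5 * (motif_call.confidence + 1.0 / (1.0 + (knn_distance or 0.0)))
    regio = REGIOSELECTIVITY.get(knn_label, "NA")
    return CallResult(motif_call.query_id, knn_label, regio, votes, confidence)
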