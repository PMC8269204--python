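"""Bundled reference tables and a synthetic halogenase-family generator.

Two kinds of fixtures make every stage testable without downloads:

* transcribed tables — the catalogue of experimentally characterized
  halogenases (cluster, regioselectivity, Trp1-4 motif strings) and the
  13 seed accessions used for homology-model construction;
* a synthetic protein family — per-cluster consensus sequences built from a
  shared scaffold with the catalogue's motif strings planted at fixed
  positions and cluster-specific drift elsewhere, from which seed-style
  alignments, profile sets, positive query sets and random decoys are
  sampled deterministically.

The synthetic family emulates the statistical structure the real analysis
relies on — a conserved common backbone, invariant functional motifs, and
cluster-level divergence — at realistic protein length (470 residues).  It
is gap-free by construction; indel behaviour is exercised by separate toy
alignments in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .group_profiles import GROUP_ORDER, GroupProfile, Reference, build_group_profile, feature_vector
from .motif_caller import MotifSet, motifset
from .seqio import AMINO_ACIDS, MultipleAlignment, SequenceRecord

#: Clusters with their own synthetic consensus sequence.
CLASSES = ("A1", "A2", "B1", "B2", "C", "phenolic", "pyrrole")

#: Map from substrate group (profile space) to the clusters whose rows seed it.
GROUP_CLASSES = {
    "5-Trp": ("B1",),
    "6-Trp": ("A2", "B2"),
    "7-Trp": ("A1",),
    "indole": ("C",),
    "phenolic": ("phenolic",),
    "pyrrole": ("pyrrole",),
}

SCAFFOLD_LENGTH = 470
#: 1-based start positions of the planted functional sites.
MOTIF_POSITIONS = {
    "FAD1": 12, "FAD2": 40, "Trp1": 50, "K": 79, "Trp2": 101, "Trp3": 160,
    "FAD3": 200, "FAD4": 240, "halide": 300, "Trp4": 443,
}
#: Sites shared by every cluster (cofactor/halide machinery).
COMMON_MOTIFS = {
    "FAD1": "GAGPAG", "FAD2": "DALIVG", "K": "WKS",
    "FAD3": "DSLFAG", "FAD4": "FLEYSR", "halide": "WIWSIP",
}
#: Cluster-specific tryptophan-binding motifs (representatives of each cluster).
CLASS_MOTIFS = {
    "A1": {"Trp1": "ATIPSL", "Trp2": "HLFGN", "Trp4": "YYETFDFEFKNFWLNGNYY"},
    "A2": {"Trp1": "ATVPNL", "Trp2": "HPFGL", "Trp4": "YYGNFEAEFRNFWTNGSYY"},
    "B1": {"Trp1": "ATFSTV", "Trp2": "HPFER", "Trp3": "QRAQ", "Trp4": "YYHGFETYS"},
    "B2": {"Trp1": "ATFSDI", "Trp2": "HPFEQ", "Trp3": "QGKTQ", "Trp4": "YYHGLPPYS"},
    "C": {"Trp1": "ATIPTI", "Trp2": "HPFGL"},
    "phenolic": {},
    "pyrrole": {},
}

_CLASS_DRIFT = {"A1": 0.15, "A2": 0.15, "B1": 0.15, "B2": 0.15, "C": 0.20,
                "phenolic": 0.30, "pyrrole": 0.30}

_AA = np.array(list(AMINO_ACIDS))


# --- transcribed tables --------------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    enzyme: str
    group: str  # A1 / A2 / B1 / B2 / C
    regioselectivity: str  # "7" / "6" / "5" / "NA"
    trp1: str | None
    trp2: str | None
    trp3: str | None
    trp4: str | None

    def to_motifset(self) -> MotifSet:
        return motifset(self.enzyme, self.trp1, self.trp2, self.trp3, self.trp4)


def _read_data(name: str) -> list[list[str]]:
    text = resources.files("halomotif.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows[1:]  # drop header


def table1_dataset() -> list[Table1Row]:
    """The transcribed catalogue of characterized halogenases."""
    out = []
    for group, enzyme, regio, t1, t2, t3, t4 in _read_data("table1.tsv"):
        out.append(Table1Row(
            enzyme=enzyme, group=group, regioselectivity=regio,
            trp1=None if t1 == "-" else t1, trp2=None if t2 == "-" else t2,
            trp3=None if t3 == "-" else t3, trp4=None if t4 == "-" else t4,
        ))
    return out


def seed_manifest() -> list[tuple[str, str]]:
    """The 13 (enzyme, accession) pairs of the homology-model seed set."""
    return [(name, acc) for name, acc in _read_data("seed_accessions.tsv")]


# --- synthetic family ----------------------------------------------------

def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator,
            protect: np.ndarray | None = None, to_different: bool = False) -> np.ndarray:
    """Substitute positions independently at ``rate`` with uniform residues."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if protect is not None:
        hit &= ~protect
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return out
    repl = _AA[rng.integers(0, 20, size=len(idx))]
    if to_different:
        for k, i in enumerate(idx):
            while repl[k] == out[i]:
                repl[k] = _AA[rng.integers(0, 20)]
    out[idx] = repl
    return out


def _motif_mask(cls: str) -> np.ndarray:
    mask = np.zeros(SCAFFOLD_LENGTH, dtype=bool)
    for site, text in {**COMMON_MOTIFS, **CLASS_MOTIFS[cls]}.items():
        start = MOTIF_POSITIONS[site] - 1
        mask[start : start + len(text)] = True
    return mask


def class_consensus(cls: str, seed: int = 0) -> str:
    """Deterministic consensus sequence of one synthetic cluster.

    A shared scaffold (drawn once from the seed) receives cluster-specific
    drift at 15-30% of non-motif positions, then the cluster's functional
    motifs are planted at their fixed coordinates.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
    scaffold = _AA[_rng(seed, 0).integers(0, 20, size=SCAFFOLD_LENGTH)]
    drift_rng = _rng(seed, 1 + CLASSES.index(cls))
    seq = _mutate(scaffold, _CLASS_DRIFT[cls], drift_rng,
                  protect=_motif_mask(cls), to_different=True)
    for site, text in {**COMMON_MOTIFS, **CLASS_MOTIFS[cls]}.items():
        start = MOTIF_POSITIONS[site] - 1
        seq[start : start + len(text)] = list(text)
    return "".join(seq)


def class_alignment(
    cls: str,
    n_rows: int = 12,
    seed: int = 0,
    motif_noise: float = 0.005,
    scaffold_noise: float = 0.30,
) -> MultipleAlignment:
    """A gap-free seed-style alignment for one cluster.

    Non-motif columns vary between rows (``scaffold_noise``) so the entropy
    screen has contrast; motif columns stay nearly invariant
    (``motif_noise``), as in real seed alignments of this family.
    """
    cons = np.array(list(class_consensus(cls, seed)))
    mask = _motif_mask(cls)
    rng = _rng(seed, 100 + CLASSES.index(cls))
    ids, rows = [], []
    for r in range(n_rows):
        row = _mutate(cons, scaffold_noise, rng, protect=mask)
        row = _mutate(row, motif_noise, rng, protect=~mask)
        ids.append(f"{cls}_seed{r + 1}")
        rows.append("".join(row))
    return MultipleAlignment(ids, rows)


def build_synthetic_profiles(
    seed: int = 0, n_rows_per_class: int = 12, pseudocount: float = 1.0
) -> dict[str, GroupProfile]:
    """The six substrate-group profiles of the synthetic family."""
    profiles = {}
    for group in GROUP_ORDER:
        ids, rows = [], []
        for cls in GROUP_CLASSES[group]:
            aln = class_alignment(cls, n_rows=n_rows_per_class, seed=seed)
            ids.extend(aln.ids)
            rows.extend(aln.rows)
        profiles[group] = build_group_profile(
            MultipleAlignment(ids, rows), group, pseudocount=pseudocount
        )
    return profiles


def make_references(
    profiles: dict[str, GroupProfile], seed: int = 0,
    classes: tuple[str, ...] = ("A1", "A2", "B1", "B2", "C"),
) -> list[Reference]:
    """Labelled reference feature vectors: one per cluster consensus."""
    refs = []
    for cls in classes:
        rec = SequenceRecord(f"ref_{cls}", class_consensus(cls, seed))
        fv = feature_vector(rec, profiles)
        refs.append(Reference(id=rec.id, label=cls, values=tuple(fv.values)))
    return refs


def sample_from_profile(
    profile: GroupProfile,
    substitution_rate: float,
    n: int,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Positive query sequences: profile consensus plus uniform substitutions.

    Each sequence starts from the profile's column-wise argmax consensus;
    every position is then independently replaced with probability
    ``substitution_rate`` by a residue drawn uniformly from the 20-letter
    alphabet (which may coincide with the original).  Records carry the
    generating group in their description.
    """
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must lie in [0, 1]")
    cons = np.array(list(AMINO_ACIDS))[profile.probabilities.argmax(axis=1)]
    rng = _rng(seed, 777)
    out = []
    for i in range(n):
        seq = cons.copy()
        hit = rng.random(len(seq)) < substitution_rate
        idx = np.nonzero(hit)[0]
        seq[idx] = _AA[rng.integers(0, 20, size=len(idx))]
        out.append(SequenceRecord(
            f"{profile.group}_sample{i + 1}", "".join(seq),
            description=f"group={profile.group}",
        ))
    return out


def sample_from_class(
    cls: str, substitution_rate: float, n: int, seed: int = 0, family_seed: int = 0
) -> list[SequenceRecord]:
    """Like :func:`sample_from_profile` but from a cluster consensus."""
    cons = np.array(list(class_consensus(cls, family_seed)))
    rng = _rng(seed, 888 + CLASSES.index(cls))
    out = []
    for i in range(n):
        seq = cons.copy()
        idx = np.nonzero(rng.random(len(seq)) < substitution_rate)[0]
        seq[idx] = _AA[rng.integers(0, 20, size=len(idx))]
        out.append(SequenceRecord(f"{cls}_q{i + 1}", "".join(seq),
                                  description=f"class={cls}"))
    return out


def make_decoys(n: int, length: int = SCAFFOLD_LENGTH, seed: int = 0) -> list[SequenceRecord]:
    """Random decoy proteins: i.i.d. uniform residues."""
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    rng = _rng(seed, 999)
    return [
        SequenceRecord(f"decoy{i + 1}",
                       "".join(_AA[rng.integers(0, 20, size=length)]),
                       description="decoy")
        for i in range(n)
    ]
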