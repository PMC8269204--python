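"""End-to-end screening pipeline: build -> scan -> embed/classify -> call.

Stages mirror the sequence-collection workflow for halogenase discovery:
a family profile HMM screens candidate proteins; survivors are embedded by
per-group positional probabilities and classified by nearest neighbour;
conserved-region maps derived from the seed alignments drive motif
extraction; and the motif grammar, arbitrated against the neighbour label,
yields the final group/regioselectivity calls.

All outputs are TSV with a '#'-prefixed header carrying the tool version and
a hash of the configuration, so a run is auditable and reruns are
byte-identical given identical inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fixtures import CLASSES, GROUP_CLASSES, class_alignment, make_references
from .group_profiles import (
    GROUP_ORDER, GroupProfile, Reference, embed_tsne, feature_vector, knn_classify,
)
from .motif_caller import (
    classify_by_motifs, consensus_call, extract_motifs, site_columns_from_regions,
)
from .motif_discovery import entropy_track, find_conserved_regions, label_sites, load_anchor_table
from .profile_hmm import ProfileHMM, build_phmm, calibrate_evalue, scan_proteome, viterbi_align
from .seqio import MultipleAlignment, ParseError, read_alignment, read_fasta, write_tsv

BUNDLE_SCHEMA = 1
CALL_CLASSES = ("A1", "A2", "B1", "B2", "C")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Pipeline configuration; the RNG seed is mandatory."""

    seed: int
    e_max: float = 1e-130
    cov_min: float = 0.5
    tau: float = 1.0
    perplexity: float = 10.0
    n_iter: int = 1000
    n_shuffles: int = 200
    synthetic: bool = True
    class_alignments: dict[str, str] = field(default_factory=dict)
    alignment_dialect: str = "aligned-fasta"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an RNG seed")
        for name in ("e_max", "cov_min", "tau", "perplexity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FamilyBundle:
    """Everything needed to classify candidates: profiles, models, site maps."""

    group_profiles: dict[str, GroupProfile]
    class_models: dict[str, ProfileHMM]
    class_alignments: dict[str, MultipleAlignment]
    site_maps: dict[str, dict[str, list[int]]]
    references: list[Reference]
    regions: dict[str, list]  # per class, labelled ConservedRegion lists

    def save(self, path) -> None:
        payload = {
            "schema_version": BUNDLE_SCHEMA,
            "group_profiles": {
                g: {
                    "probabilities": p.probabilities.tolist(),
                    "column_map": p.column_map.tolist(),
                    "model": json.loads(p.model.to_json()),
                }
                for g, p in self.group_profiles.items()
            },
            "class_models": {c: json.loads(m.to_json()) for c, m in self.class_models.items()},
            "site_maps": self.site_maps,
            "references": [
                {"id": r.id, "label": r.label, "values": list(r.values)}
                for r in self.references
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FamilyBundle":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema_version") != BUNDLE_SCHEMA:
            raise PipelineError(f"unsupported bundle schema {payload.get('schema_version')!r}")
        gps = {}
        for g, d in payload["group_profiles"].items():
            model = ProfileHMM.from_json(json.dumps(d["model"]))
            gps[g] = GroupProfile(
                group=g,
                probabilities=np.asarray(d["probabilities"], dtype=float),
                column_map=np.asarray(d["column_map"], dtype=np.int64),
                model=model,
            )
        return cls(
            group_profiles=gps,
            class_models={c: ProfileHMM.from_json(json.dumps(d))
                          for c, d in payload["class_models"].items()},
            class_alignments={},
            site_maps={c: {s: list(map(int, nodes)) for s, nodes in m.items()}
                       for c, m in payload["site_maps"].items()},
            references=[Reference(r["id"], r["label"], tuple(r["values"]))
                        for r in payload["references"]],
            regions={},
        )


def build_family_bundle(config: RunConfig) -> FamilyBundle:
    """Build profiles, class models, conserved-region maps and references."""
    anchors = load_anchor_table()
    if config.synthetic:
        alignments = {c: class_alignment(c, seed=config.seed) for c in CLASSES}
    else:
        if not config.class_alignments:
            raise PipelineError("stage build: config.synthetic is false but no "
                                "class alignment paths were given")
        alignments = {
            c: read_alignment(p, config.alignment_dialect)
            for c, p in config.class_alignments.items()
        }
    profiles: dict[str, GroupProfile] = {}
    for group in GROUP_ORDER:
        members = [alignments[c] for c in GROUP_CLASSES[group] if c in alignments]
        if not members:
            raise PipelineError(f"stage build: no seed alignment for group {group}")
        ids = [i for m in members for i in m.ids]
        rows = [r for m in members for r in m.rows]
        from .group_profiles import build_group_profile
        profiles[group] = build_group_profile(MultipleAlignment(ids, rows), group)

    class_models, site_maps, regions = {}, {}, {}
    for c in CALL_CLASSES:
        if c not in alignments:
            continue
        aln = alignments[c]
        model = build_phmm(aln)
        track = entropy_track(aln)
        regs = label_sites(
            find_conserved_regions(track, tau=config.tau), aln, anchors
        )
        class_models[c] = model
        site_maps[c] = site_columns_from_regions(regs, aln, anchors, model)
        regions[c] = regs

    if config.synthetic:
        references = make_references(profiles, seed=config.seed)
    else:
        references = make_references(profiles, seed=config.seed,
                                     classes=tuple(c for c in CALL_CLASSES if c in alignments))
    return FamilyBundle(profiles, class_models, alignments, site_maps, references, regions)


def call_sequences(bundle: FamilyBundle, queries, seed: int = 0):
    """Motif-grammar + nearest-neighbour consensus calls for each query.

    The query's motifs are extracted against the class model it aligns to
    best (Viterbi score); the 1-NN label on raw feature vectors serves as
    the fallback for ambiguous grammar votes.
    """
    results = []
    for q in queries:
        scores = {c: viterbi_align(m, q).score_bits for c, m in bundle.class_models.items()}
        best_class = max(sorted(scores), key=lambda c: scores[c])
        motifs = extract_motifs(q, bundle.class_models[best_class],
                                bundle.site_maps[best_class])
        motif_call = classify_by_motifs(motifs)
        try:
            fv = feature_vector(q, bundle.group_profiles)
            label, dist = knn_classify(fv.values, bundle.references)
        except Exception:
            label, dist, fv = None, None, None
        results.append((q, motifs, consensus_call(motif_call, label, dist), fv))
    return results


def run_pipeline(config: RunConfig, fasta_path, out_dir) -> Path:
    """Run the full pipeline and write hits/features/embedding/regions/calls.

    Any stage failure raises :class:`PipelineError` naming the stage; TSVs
    written by earlier stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"halomotif {__version__}", f"config {config.digest()}", f"seed {config.seed}"]
    log_lines = list(header)

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name}: {exc}") from exc

    bundle = stage("build", lambda: build_family_bundle(config))
    log_lines.append(f"build: {len(bundle.group_profiles)} group profiles, "
                     f"{len(bundle.class_models)} class models")

    try:
        queries = read_fasta(fasta_path)
    except ParseError as exc:
        if "no FASTA records" not in str(exc):
            raise PipelineError(f"stage read: {exc}") from exc
        queries = []
        log_lines.append("warning: empty query FASTA; writing empty outputs")

    # regions are input-independent; write them first
    region_rows = [
        (c, r.start_col, r.end_col, r.label, f"{r.mean_entropy:.4f}", f"{r.gap_fraction:.4f}")
        for c in sorted(bundle.regions) for r in bundle.regions[c]
    ]
    write_tsv(out / "regions.tsv",
              ["class", "start_col", "end_col", "label", "mean_entropy", "gap_fraction"],
              region_rows, header)

    def do_scan():
        ids, rows = [], []
        for c in ("A1", "A2", "B1", "B2"):
            aln = bundle.class_alignments.get(c)
            if aln is not None:
                ids.extend(aln.ids)
                rows.extend(aln.rows)
        model = build_phmm(MultipleAlignment(ids, rows))
        calib = calibrate_evalue(model, n_shuffles=config.n_shuffles, seed=config.seed)
        return scan_proteome(model, queries, calib,
                             e_max=config.e_max, cov_min=config.cov_min)

    hits = stage("scan", do_scan) if queries else []
    write_tsv(out / "hits.tsv",
              ["query_id", "bit_score", "e_value", "coverage", "q_start", "q_end"],
              [(h.query_id, f"{h.bit_score:.2f}", f"{h.e_value:.3e}",
                f"{h.model_coverage:.4f}", h.aligned_interval[0], h.aligned_interval[1])
               for h in hits], header)
    log_lines.append(f"scan: {len(hits)}/{len(queries)} queries retained "
                     f"(e_max={config.e_max:g}, cov_min={config.cov_min:g})")

    retained = {h.query_id for h in hits}
    kept = [q for q in queries if q.id in retained]
    calls = stage("call", lambda: call_sequences(bundle, kept, seed=config.seed)) if kept else []

    features = [fv for _, _, _, fv in calls if fv is not None]
    write_tsv(out / "features.tsv", ["query_id", "values"],
              [(fv.query_id, ",".join(f"{v:.5f}" for v in fv.values)) for fv in features],
              header)

    emb_rows = []
    if len(features) >= 3 * config.perplexity:
        points = stage("embed", lambda: embed_tsne(
            features, perplexity=config.perplexity, n_iter=config.n_iter, seed=config.seed))
        by_id = {c[0].id: c[2] for c in calls}
        emb_rows = [(p.query_id, f"{p.x:.4f}", f"{p.y:.4f}", by_id[p.query_id].group)
                    for p in points]
    else:
        log_lines.append("embed: skipped (too few points for the perplexity); "
                         "classification used raw feature vectors")
    write_tsv(out / "embedding.tsv", ["query_id", "x", "y", "class"], emb_rows, header)

    call_rows = []
    for q, motifs, call, _ in calls:
        evidence = ";".join(f"{v.rule}:{'+'.join(v.groups)}:{v.evidence}" for v in call.votes)
        call_rows.append((
            q.id, call.group, call.regioselectivity, f"{call.confidence:.3f}",
            motifs.trp1 or "-", motifs.trp2 or "-", motifs.trp3 or "-", motifs.trp4 or "-",
            evidence,
        ))
    write_tsv(out / "calls.tsv",
              ["query_id", "group", "regioselectivity", "confidence",
               "trp1", "trp2", "trp3", "trp4", "evidence"],
              call_rows, header)
    log_lines.append(f"call: {len(call_rows)} calls written")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
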