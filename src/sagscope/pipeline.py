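"""End-to-end orchestration: simulate -> qc -> completeness -> recruit ->
islands -> bsr -> phylotype/screen, driven by a single YAML config with one
global seed.

The global seed is fanned out to per-stage seeds by a stable CRC32 hash of
the stage name, so toggling stages never changes the random stream of the
stages that still run. Every output is plain text (FASTA/TSV/BED/JSON) and
the run manifest records a SHA-256 checksum and wall time per stage;
re-running with an identical config reproduces identical checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seq import stage_seed
from .bsr import bsr, bsr_summary
from .completeness import OccurrenceMatrix, completeness_table, derive_cscgs
from .io import write_bed, write_fasta, write_tsv
from .islands import CodingLocus, call_islands, cog_enrichment
from .phylotypes import cluster_phylotypes, screen_table, summarize_screen
from .qc import filter_reads
from .recruitment import abundance_matrix, recruit
from .synthetic import (
    CommunityMember,
    make_genome,
    make_metagenome,
    make_occurrence_matrix,
    make_proteome_triplet,
    make_sag_assembly,
    make_ssu_clouds,
    place_family_loci,
)

STAGES = ("simulate", "qc", "completeness", "recruit", "islands", "bsr", "phylotype", "screen")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "sagscope_out",
    "stages": list(STAGES),
    "simulate": {
        "n_genomes": 3,
        "genome_length": 60000,
        "gc": 0.34,
        "samples": [
            {"sample_id": "s200m", "depth_m": 200.0},
            {"sample_id": "s500m", "depth_m": 500.0},
            {"sample_id": "s800m", "depth_m": 800.0},
        ],
        "peak_depths": [200.0, 500.0, 800.0],
        "depth_scale": 250.0,
        "n_reads": 3000,
        "read_len_range": [100, 800],
        "junk": [0.05, 0.05, 0.05, 0.05],
        "divergence": 0.0,
        "sag_completeness": 0.5,
        "sag_n_contigs": 10,
        "n_markers": 94,
        "occurrence": {"n_genomes": 60, "n_accessory": 60, "dropout": 0.005, "dup_rate": 0.005},
        "islands": {"n_loci": 60, "locus_len": 500, "n_islands": 8},
        "proteomes": [10, 10, 10, 10],
        "ssu": {"n_clouds": 4, "members_per_cloud": [6, 5, 5, 4], "seq_len": 1200},
        "screen_sites": [
            {"site": "South Atlantic", "depth_m": 800, "n_sags": 67, "amoA": 0.60, "nirK": 0.48},
            {"site": "North Pacific", "depth_m": 770, "n_sags": 52, "amoA": 0.81, "nirK": 0.62},
        ],
    },
    "qc": {"min_len": 100, "min_entropy": 70.0, "drop_ambiguous": True, "dedupe": True},
    "completeness": {"threshold": 0.98},
    "recruit": {"min_aln_len": 200, "min_identity": 0.95},
    "islands": {"alpha": 0.05},
    "bsr": {"threshold": 0.4},
    "phylotype": {"threshold": 0.99},
}

_RANGES = {
    ("qc", "min_len"): (3, 10000),
    ("qc", "min_entropy"): (0.0, 100.0),
    ("completeness", "threshold"): (1e-9, 1.0),
    ("recruit", "min_aln_len"): (1, 100000),
    ("recruit", "min_identity"): (0.0, 1.0),
    ("islands", "alpha"): (0.0, 1.0),
    ("bsr", "threshold"): (0.0, 1.0),
    ("phylotype", "threshold"): (0.0, 1.0),
    ("simulate", "gc"): (0.2, 0.8),
    ("simulate", "divergence"): (0.0, 0.25),
    ("simulate", "sag_completeness"): (1e-9, 1.0),
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            errors.append(f"unknown key {path}{key}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, f"{path}{key}.", errors)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(config: dict | None) -> dict:
    """Merge a (possibly partial) config onto the defaults, rejecting
    unknown keys and out-of-range parameters. Raises ConfigError with an
    aggregated, human-readable message."""
    errors: list[str] = []
    merged = _merge(DEFAULT_CONFIG, config or {}, "", errors)
    for (section, key), (lo, hi) in _RANGES.items():
        val = merged[section][key]
        if not isinstance(val, (int, float)) or not lo <= val <= hi:
            errors.append(f"{section}.{key} = {val!r} outside [{lo}, {hi}]")
    unknown_stages = set(merged["stages"]) - set(STAGES)
    if unknown_stages:
        errors.append(f"unknown stages: {sorted(unknown_stages)}")
    if not isinstance(merged["seed"], int) or merged["seed"] < 0:
        errors.append(f"seed must be a non-negative integer, got {merged['seed']!r}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return merged


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _depth_abundances(peak_depths, depth, scale) -> np.ndarray:
    w = np.exp(-(((np.asarray(peak_depths, dtype=float) - depth) / scale) ** 2))
    return w / w.sum()


def run_pipeline(config: dict, log=print) -> dict:
    """Run the configured stages in dependency order; returns the manifest
    (also written to <outdir>/manifest.json)."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    stages = [s for s in STAGES if s in cfg["stages"]]
    manifest: dict = {"version": __version__, "config": cfg, "stages": {}}
    state: dict = {}

    for stage in stages:
        t0 = time.perf_counter()
        log(f"[{stage}] starting")
        try:
            outputs = _STAGE_FNS[stage](cfg, seed, outdir, state)
        except KeyError as exc:
            raise RuntimeError(
                f"stage {stage!r} failed: missing upstream result {exc}; "
                "did you disable a stage it depends on?"
            ) from exc
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        entry = {"outputs": {}, "wall_time_s": round(time.perf_counter() - t0, 3)}
        for p in outputs:
            entry["outputs"][p.name] = _sha256(p)
        manifest["stages"][stage] = entry
        log(f"[{stage}] done in {entry['wall_time_s']}s ({len(outputs)} outputs)")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: dict, seed: int, outdir: Path, state: dict) -> list[Path]:
    sim = cfg["simulate"]
    s = stage_seed(seed, "simulate")
    rng = np.random.default_rng(s)
    out: list[Path] = []

    genomes = {}
    for i in range(sim["n_genomes"]):
        gid = f"genome{i:02d}"
        genomes[gid] = make_genome(sim["genome_length"], sim["gc"], stage_seed(s, gid), gid)
    write_fasta([(g.genome_id, g.sequence) for g in genomes.values()], outdir / "genomes.fa")
    out.append(outdir / "genomes.fa")

    # coding loci + designated islands on the focal genome (genome00)
    isl = sim["islands"]
    focal = genomes["genome00"]
    loci_ids = [f"prot{i:03d}" for i in range(isl["n_loci"])]
    loci_pos = place_family_loci(len(focal.sequence), loci_ids, isl["locus_len"], stage_seed(s, "loci"))
    island_ids = sorted(rng.choice(loci_ids, size=isl["n_islands"], replace=False))
    cogs = {}
    cats = list("CEGHIJKLMPRSTV") + ["none", "mixed"]
    for pid in loci_ids:
        if pid in island_ids:
            cogs[pid] = str(rng.choice(["L", "M", "V"]))
        else:
            cogs[pid] = str(rng.choice(cats))
    loci = [
        CodingLocus(pid, "genome00", s0, e0, "+", cogs[pid]) for pid, (s0, e0) in loci_pos.items()
    ]
    write_bed(loci, outdir / "loci.bed")
    write_tsv(
        pd.DataFrame({"protein_id": loci_ids, "cog_category": [cogs[p] for p in loci_ids]}),
        outdir / "cogs.tsv",
    )
    write_tsv(pd.DataFrame({"protein_id": island_ids}), outdir / "island_truth.tsv")
    out += [outdir / "loci.bed", outdir / "cogs.tsv", outdir / "island_truth.tsv"]

    shields = sorted(loci_pos[pid] for pid in island_ids)
    members_proto = []
    for i, gid in enumerate(genomes):
        members_proto.append(
            {
                "genome_id": gid,
                "divergence": sim["divergence"],
                "shielded_intervals": shields if gid == "genome00" else [],
                "peak_depth": sim["peak_depths"][i % len(sim["peak_depths"])],
            }
        )

    read_files = []
    samples_meta = []
    for sample in sim["samples"]:
        sid, depth = sample["sample_id"], float(sample["depth_m"])
        abund = _depth_abundances([m["peak_depth"] for m in members_proto], depth, sim["depth_scale"])
        members = [
            CommunityMember(m["genome_id"], float(a), m["divergence"], m["shielded_intervals"])
            for m, a in zip(members_proto, abund)
        ]
        rs = make_metagenome(
            members,
            genomes,
            sim["n_reads"],
            tuple(sim["read_len_range"]),
            tuple(sim["junk"]),
            stage_seed(s, f"reads_{sid}"),
            sample_id=sid,
            depth_m=depth,
        )
        write_fasta(rs.reads, outdir / f"reads_{sid}.fa")
        truth_rows = [
            {
                "read_id": rid,
                "kind": rs.kinds[rid],
                "source_genome": rs.truth.get(rid, ("", (0, 0)))[0],
                "start": rs.truth.get(rid, ("", (0, 0)))[1][0],
                "end": rs.truth.get(rid, ("", (0, 0)))[1][1],
            }
            for rid, _ in rs.reads
        ]
        write_tsv(pd.DataFrame(truth_rows), outdir / f"truth_{sid}.tsv")
        read_files += [outdir / f"reads_{sid}.fa", outdir / f"truth_{sid}.tsv"]
        samples_meta.append({"sample_id": sid, "depth_m": depth, **{m["genome_id"]: float(a) for m, a in zip(members_proto, abund)}})
        state.setdefault("readsets", {})[sid] = rs
    write_tsv(pd.DataFrame(samples_meta), outdir / "community.tsv")
    out += read_files + [outdir / "community.tsv"]

    # marker loci + SAG assembly of the focal genome
    marker_ids = [f"COG{i:04d}" for i in range(sim["n_markers"])]
    marker_loci = place_family_loci(len(focal.sequence), marker_ids, 60, stage_seed(s, "markers"))
    sag = make_sag_assembly(
        focal,
        sim["sag_completeness"],
        sim["sag_n_contigs"],
        marker_loci,
        stage_seed(s, "sag"),
        sag_id="sagA",
    )
    write_fasta(sag.contigs, outdir / "sagA_contigs.fa")
    write_tsv(
        pd.DataFrame({"sag_id": "sagA", "family_id": sorted(sag.detected_families)}),
        outdir / "sag_families.tsv",
    )
    write_tsv(
        pd.DataFrame([{"sag_id": "sagA", "assembly_length": sag.assembly_length}]),
        outdir / "assembly_lengths.tsv",
    )
    out += [outdir / "sagA_contigs.fa", outdir / "sag_families.tsv", outdir / "assembly_lengths.tsv"]
    state["sag"] = sag
    state["genomes"] = genomes
    state["loci"] = loci
    state["island_truth"] = set(island_ids)

    occ_cfg = sim["occurrence"]
    occ = make_occurrence_matrix(
        occ_cfg["n_genomes"],
        sim["n_markers"],
        occ_cfg["n_accessory"],
        occ_cfg["dropout"],
        occ_cfg["dup_rate"],
        stage_seed(s, "occurrence"),
    )
    # planted single-copy families share ids with the SAG marker loci
    occ.family_ids = marker_ids + occ.family_ids[sim["n_markers"] :]
    write_tsv(occ.to_frame(), outdir / "occurrence.tsv", index=True)
    out.append(outdir / "occurrence.tsv")
    state["occurrence"] = occ

    q, ra, rb, ptruth = make_proteome_triplet(*sim["proteomes"], seed=stage_seed(s, "proteomes"))
    write_fasta(q, outdir / "query.faa")
    write_fasta(ra, outdir / "ref_a.faa")
    write_fasta(rb, outdir / "ref_b.faa")
    write_tsv(
        pd.DataFrame([{"protein_id": k, "category": v} for k, v in ptruth.items()]),
        outdir / "proteome_truth.tsv",
    )
    out += [outdir / "query.faa", outdir / "ref_a.faa", outdir / "ref_b.faa", outdir / "proteome_truth.tsv"]
    state["proteomes"] = (q, ra, rb, ptruth)

    ssu_cfg = sim["ssu"]
    sites = [site["site"] for site in sim["screen_sites"]]
    records, cloud_truth = make_ssu_clouds(
        ssu_cfg["n_clouds"],
        ssu_cfg["members_per_cloud"],
        sites,
        ssu_cfg["seq_len"],
        seed=stage_seed(s, "ssu"),
    )
    write_fasta([(sid, seq) for sid, seq, _ in records], outdir / "ssu.fa")
    write_tsv(
        pd.DataFrame(
            [{"seq_id": sid, "site": site, "cloud": cloud_truth[sid]} for sid, _, site in records]
        ),
        outdir / "ssu_meta.tsv",
    )
    out += [outdir / "ssu.fa", outdir / "ssu_meta.tsv"]
    state["ssu"] = records

    rows = []
    k = 0
    for site in sim["screen_sites"]:
        r = np.random.default_rng(stage_seed(s, f"screen_{site['site']}"))
        for _ in range(site["n_sags"]):
            rows.append(
                {
                    "sag_id": f"sag{k:04d}",
                    "site": site["site"],
                    "depth_m": site["depth_m"],
                    "amoA": bool(r.random() < site["amoA"]),
                    "nirK": bool(r.random() < site["nirK"]),
                }
            )
            k += 1
    detections = pd.DataFrame(rows)
    write_tsv(detections, outdir / "screen_detections.tsv")
    out.append(outdir / "screen_detections.tsv")
    state["detections"] = detections
    return out


def _stage_qc(cfg: dict, seed: int, outdir: Path, state: dict) -> list[Path]:
    q = cfg["qc"]
    out = []
    state["clean"] = {}
    for sid, rs in state["readsets"].items():
        clean, report = filter_reads(
            rs,
            min_len=q["min_len"],
            min_entropy=q["min_entropy"],
            drop_ambiguous=q["drop_ambiguous"],
            dedupe_reads=q["dedupe"],
        )
        state["clean"][sid] = clean
        write_fasta(clean.reads, outdir / f"clean_{sid}.fa")
        write_tsv(pd.DataFrame([asdict(report)]), outdir / f"qc_{sid}.tsv")
        out += [outdir / f"clean_{sid}.fa", outdir / f"qc_{sid}.tsv"]
    return out


def _stage_completeness(cfg: dict, seed: int, outdir: Path, state: dict) -> list[Path]:
    cscgs = derive_cscgs(state["occurrence"], cfg["completeness"]["threshold"])
    sag = state["sag"]
    table = completeness_table(
        {sag.sag_id: sag.detected_families},
        cscgs,
        {sag.sag_id: sag.assembly_length},
    )
    write_tsv(pd.DataFrame({"family_id": cscgs.family_ids}), outdir / "cscgs.tsv")
    write_tsv(table, outdir / "completeness.tsv")
    state["cscgs"] = cscgs
    return [outdir / "cscgs.tsv", outdir / "completeness.tsv"]


def _stage_recruit(cfg: dict, seed: int, outdir: Path, state: dict) -> list[Path]:
    r = cfg["recruit"]
    targets = dict(state["genomes"])
    hits_by = {}
    all_rows = []
    for sid, clean in state["clean"].items():
        for tid, genome in targets.items():
            hits = recruit(clean, genome, r["min_aln_len"], r["min_identity"])
            hits_by[(sid, tid)] = hits
            all_rows += [
                {"sample_id": sid, **asdict(h)} for h in hits
            ]
    hits_df = pd.DataFrame(
        all_rows,
        columns=["sample_id", "read_id", "target_id", "contig_id", "start", "end",
                 "strand", "aln_len", "identity", "score"],
    )
    write_tsv(hits_df, outdir / "hits.tsv")
    lengths = {tid: len(g.sequence) for tid, g in targets.items()}
    n_reads = {sid: len(c.reads) for sid, c in state["clean"].items()}
    am = abundance_matrix(hits_by, lengths, n_reads)
    write_tsv(am.table, outdir / "abundance.tsv", index=True)
    state["hits_by"] = hits_by
    state["abundance"] = am
    return [outdir / "hits.tsv", outdir / "abundance.tsv"]


def _stage_islands(cfg: dict, seed: int, outdir: Path, state: dict) -> list[Path]:
    # pool all samples' recruits against the focal genome
    pooled = []
    for (sid, tid), hits in state["hits_by"].items():
        if tid == "genome00":
            pooled += hits
    calls = call_islands(state["loci"], pooled, known_contigs={"genome00"})
    enrich = cog_enrichment(calls, state["loci"], cfg["islands"]["alpha"])
    write_tsv(pd.DataFrame([asdict(c) for c in calls]), outdir / "islands.tsv")
    write_tsv(pd.DataFrame([asdict(e) for e in enrich]), outdir / "enrichment.tsv")
    state["island_calls"] = calls
    return [outdir / "islands.tsv", outdir / "enrichment.tsv"]


def _stage_bsr(cfg: dict, seed: int, outdir: Path, state: dict) -> list[Path]:
    q, ra, rb, _ = state["proteomes"]
    records = bsr(q, ra, rb, cfg["bsr"]["threshold"])
    write_tsv(pd.DataFrame([asdict(r) for r in records]), outdir / "bsr.tsv")
    with open(outdir / "bsr_summary.json", "w") as fh:
        json.dump(bsr_summary(records), fh, indent=2)
    state["bsr_records"] = records
    return [outdir / "bsr.tsv", outdir / "bsr_summary.json"]


def _stage_phylotype(cfg: dict, seed: int, outdir: Path, state: dict) -> list[Path]:
    phylotypes = cluster_phylotypes(state["ssu"], cfg["phylotype"]["threshold"])
    rows = [
        {
            "phylotype_id": p.phylotype_id,
            "representative_id": p.representative_id,
            "n_members": len(p.member_ids),
            "members": ",".join(p.member_ids),
            "site_counts": json.dumps(p.site_counts, sort_keys=True),
        }
        for p in phylotypes
    ]
    write_tsv(pd.DataFrame(rows), outdir / "phylotypes.tsv")
    state["phylotypes"] = phylotypes
    return [outdir / "phylotypes.tsv"]


def _stage_screen(cfg: dict, seed: int, outdir: Path, state: dict) -> list[Path]:
    summaries = summarize_screen(state["detections"])
    write_tsv(screen_table(summaries), outdir / "screen_summary.tsv")
    return [outdir / "screen_summary.tsv"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "completeness": _stage_completeness,
    "recruit": _stage_recruit,
    "islands": _stage_islands,
    "bsr": _stage_bsr,
    "phylotype": _stage_phylotype,
    "screen": _stage_screen,
}
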