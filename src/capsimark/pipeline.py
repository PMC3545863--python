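"""End-to-end orchestration: simulate -> trim -> map -> call -> filter ->
ssr -> compare -> stats, from one flat configuration, with a provenance
manifest.

The manifest is JSON-lines: one record per stage with the parameters used,
input digests and record counts (reads in/retained, SNP candidates/kept
with per-flag rejection counts, SSRs perfect/compound). Identical seeds
yield identical manifests. ``self_test`` runs the planted-truth recovery
suite plus the self-contained arithmetic checks and prints a pass/fail
table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import yaml

from . import snp_discovery as snp
from . import ssr_discovery as ssr
from . import marker_compare as mc
from . import summary_stats as stats_mod
from .io_formats import (
    read_fasta, read_junction_tsv, write_sam, write_snp_vcf, write_table,
)
from .preprocess import TrimReport, trim_stream
from .synthetic_data import (
    MapStats, SimConfig, naive_map, simulate_reads, simulate_truth,
    write_reads, write_truth,
)

logger = logging.getLogger("capsimark")

ALL_STAGES = ("simulate", "trim", "map", "snp", "ssr", "compare", "stats")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; every method constant is a named key."""

    seed: int = 0
    out_dir: str = "capsimark_run"
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    trim_policy: str = "normal"
    mapper_k: int = 21
    min_line_depth: int = snp.DEFAULT_MIN_LINE_DEPTH
    hom_fraction: float = snp.DEFAULT_HOM_FRACTION
    het_min_count: int = snp.DEFAULT_HET_MIN_COUNT
    filter_window: int = snp.DEFAULT_WINDOW
    total_min_depth: int = snp.DEFAULT_TOTAL_MIN_DEPTH
    depth_mode: str = "summed"
    max_spacer: int = ssr.DEFAULT_MAX_SPACER
    window_min_matches: int = mc.DEFAULT_MIN_MATCHES
    junctions_path: str | None = None  # required for snp stage if no simulate

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" in self.stages and self.seed is None:
            raise ValueError("seed is mandatory when simulation is enabled")

    @classmethod
    def from_flat(cls, flat: Mapping[str, object]) -> "RunConfig":
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        run_fields = {f.name: f for f in dataclasses.fields(cls)}
        sim_kwargs: dict[str, object] = {}
        run_kwargs: dict[str, object] = {}
        for key, val in flat.items():
            if key in sim_fields and key != "seed":
                sim_kwargs[key] = val
            elif key == "stages":
                if isinstance(val, str):
                    val = val.split(",")
                run_kwargs["stages"] = tuple(str(s).strip() for s in val)
            elif key in run_fields:
                default = run_fields[key].default
                cast = type(default) if default is not None and not isinstance(
                    default, (tuple, SimConfig)) else str
                run_kwargs[key] = cast(val)  # type: ignore[operator]
            else:
                raise KeyError(f"unknown config key {key!r}")
        seed = int(run_kwargs.get("seed", 0))
        sim_kwargs.setdefault("seed", seed)
        run_kwargs["sim"] = SimConfig.from_flat(sim_kwargs)
        return cls(**run_kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        return cls.from_flat(flat)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    Any stage failure raises PipelineError naming the stage, after writing
    the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "seed": config.seed,
            "stages": list(config.stages),
            "trim_policy": config.trim_policy,
            "mapper_k": config.mapper_k,
            "min_line_depth": config.min_line_depth,
            "hom_fraction": config.hom_fraction,
            "het_min_count": config.het_min_count,
            "filter_window": config.filter_window,
            "total_min_depth": config.total_min_depth,
            "depth_mode": config.depth_mode,
            "max_spacer": config.max_spacer,
            "window_min_matches": config.window_min_matches,
            "sim": {k: list(v) if isinstance(v, tuple) else v
                    for k, v in dataclasses.asdict(config.sim).items()},
        },
        "stages": {},
    }
    state: dict = {}

    def record(stage: str, counts: dict) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    def write_manifest() -> None:
        with open(out / "manifest.jsonl", "w") as fh:
            fh.write(json.dumps({"parameters": manifest["parameters"]},
                                sort_keys=True) + "\n")
            for stage, counts in manifest["stages"].items():
                fh.write(json.dumps({"stage": stage, **counts}, sort_keys=True)
                         + "\n")

    stage_fns: dict[str, Callable[[], None]] = {
        "simulate": lambda: _stage_simulate(config, out, state, record),
        "trim": lambda: _stage_trim(config, out, state, record),
        "map": lambda: _stage_map(config, out, state, record),
        "snp": lambda: _stage_snp(config, out, state, record),
        "ssr": lambda: _stage_ssr(config, out, state, record),
        "compare": lambda: _stage_compare(config, out, state, record),
        "stats": lambda: _stage_stats(config, out, state, record),
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            stage_fns[stage]()
        except Exception as exc:
            write_manifest()
            raise PipelineError(stage, exc) from exc
    write_manifest()
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, state: dict, record) -> None:
    sim = dataclasses.replace(config.sim, seed=config.seed)
    truth = simulate_truth(sim)
    reads = simulate_reads(truth, sim)
    paths = write_truth(truth, out)
    read_paths = write_reads(reads, out)
    state.update(truth=truth, reads=reads, sim=sim)
    record("simulate", {
        "n_contigs": len(truth.contigs),
        "total_nt": sum(len(c) for c in truth.contigs),
        "n_junctions": len(truth.junctions),
        "n_planted_snps": len(truth.snps()),
        "n_planted_het": len(truth.het_positions()),
        "n_planted_ssrs": len(truth.ssrs),
        "n_reads": {g: len(r) for g, r in reads.items()},
        "digests": {k: _digest(p) for k, p in {**paths, **read_paths}.items()},
    })


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise RuntimeError(f"stage {stage!r} requires outputs of an earlier "
                           f"stage providing {key!r}; enable it or supply inputs")
    return state[key]


def _stage_trim(config: RunConfig, out: Path, state: dict, record) -> None:
    reads = _require(state, "reads", "trim")
    trimmed: dict[str, list] = {}
    counts = {}
    for g, lst in reads.items():
        rep = TrimReport()
        trimmed[g] = list(trim_stream(lst, config.trim_policy, rep))
        counts[g] = {"input": rep.n_input, "retained": rep.n_retained}
    state["trimmed"] = trimmed
    record("trim", {"policy": config.trim_policy, "per_genotype": counts})


def _stage_map(config: RunConfig, out: Path, state: dict, record) -> None:
    truth = _require(state, "truth", "map")
    reads = state.get("trimmed") or _require(state, "reads", "map")
    alignments = []
    counts = {}
    for g, lst in reads.items():
        ms = MapStats()
        alignments.extend(naive_map(lst, truth.contigs, g, k=config.mapper_k,
                                    stats=ms))
        counts[g] = dataclasses.asdict(ms)
    write_sam(alignments, truth.contig_lengths(), out / "alignments.sam")
    state["alignments"] = alignments
    record("map", {"per_genotype": counts, "n_alignments": len(alignments)})


def _stage_snp(config: RunConfig, out: Path, state: dict, record) -> None:
    truth = _require(state, "truth", "snp")
    alignments = _require(state, "alignments", "snp")
    if config.junctions_path:
        jpath = Path(config.junctions_path)
        if not jpath.exists():
            raise FileNotFoundError(
                f"junction file {jpath} required by the snp stage is missing")
        junctions = read_junction_tsv(jpath)
    else:
        junctions = truth.junctions
    pile = snp.build_pileup(alignments, truth.contigs,
                            genotypes=list(truth.config.genotype_names))
    rows = snp.genotype_rows(pile, truth.contigs, config.min_line_depth,
                             config.hom_fraction, config.het_min_count)
    candidates, het_track = snp.call_iga_snps(rows)
    kept, flagged = snp.filter_iga_snps(
        candidates, het_track, junctions, config.filter_window,
        config.total_min_depth, config.depth_mode)
    write_snp_vcf(kept + flagged, truth.contig_lengths(), out / "snps.vcf",
                  emit_all=True)
    write_table(snp.snp_frame(kept + flagged), out / "snps.tsv")
    state.update(kept_snps=kept, flagged_snps=flagged, het_track=het_track,
                 pileup=pile)
    flag_counts: dict[str, int] = {}
    for s in flagged:
        for f in s.filter_flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
    record("snp", {
        "candidates": len(candidates), "kept": len(kept),
        "flagged": len(flagged), "het_positions": len(het_track),
        "flag_counts": flag_counts,
        "skipped_overrun": pile.skipped_overrun,
    })


def _stage_ssr(config: RunConfig, out: Path, state: dict, record) -> None:
    truth = _require(state, "truth", "ssr")
    perfect_all, compound_all = [], []
    tasks = []
    for contig in truth.contigs:
        found = ssr.find_perfect_ssrs(contig.sequence, contig_id=contig.id)
        perfect, compounds = ssr.merge_compound(found, config.max_spacer,
                                                contig.sequence)
        perfect_all.extend(perfect)
        compound_all.extend(compounds)
        for rec in perfect:
            tasks.append(ssr.make_primer3_input(rec, contig))
    write_table(ssr.ssr_frame(perfect_all, compound_all), out / "ssr.tsv")
    with open(out / "primer3_input.txt", "w") as fh:
        for t in tasks:
            fh.write(t.to_boulder())
    state.update(ssrs_perfect=perfect_all, ssrs_compound=compound_all)
    record("ssr", {"perfect": len(perfect_all), "compound": len(compound_all),
                   "primer_tasks": len(tasks)})


def _stage_compare(config: RunConfig, out: Path, state: dict, record) -> None:
    """Reciprocal window comparison of the called SNP set against the
    planted clean set — the recovered and planted marker sets should
    coincide on clean simulations."""
    truth = _require(state, "truth", "compare")
    kept = _require(state, "kept_snps", "compare")
    seqs = {c.id: c for c in truth.contigs}
    windows_called = [mc.extract_window(seqs[s.contig_id], s.pos)
                      for s in kept]
    windows_truth = [mc.extract_window(seqs[v.contig_id], v.pos,
                                       snp_id=f"truth:{v.contig_id}:{v.pos}")
                     for v in truth.snps(kinds=("clean",))]
    result = mc.compare_snp_sets(windows_called, windows_truth,
                                 config.window_min_matches)
    rows = ([{"snp_id": a, "status": "common", "partner": b, "n_matches": m}
             for a, b, m in result.common]
            + [{"snp_id": i, "status": "unique_A", "partner": "", "n_matches": 0}
               for i in result.unique_a]
            + [{"snp_id": i, "status": "unique_B", "partner": "", "n_matches": 0}
               for i in result.unique_b])
    import pandas as pd
    write_table(pd.DataFrame(rows), out / "comparison.tsv")
    record("compare", {"common": result.n_common,
                       "unique_called": result.n_unique_a,
                       "unique_planted": result.n_unique_b})


def _stage_stats(config: RunConfig, out: Path, state: dict, record) -> None:
    truth = _require(state, "truth", "stats")
    st = stats_mod.assembly_stats(truth.contigs)
    write_table(st.to_frame(), out / "stats.tsv")
    counts = {"n_contigs": st.n_contigs, "total_nt": st.total_nt,
              "gc_pct": st.gc_pct, "n50": st.n50}
    kept = state.get("kept_snps")
    if kept is not None:
        dens = stats_mod.snp_density(st.total_nt, len(kept), st.n_contigs)
        counts["bases_per_snp"] = dens.bases_per_marker
        counts["snps_per_contig"] = dens.markers_per_contig
    record("stats", counts)


# ---------------------------------------------------------------------------
# self test
# ---------------------------------------------------------------------------

def self_test(seed: int = 42, hom_fraction: float = snp.DEFAULT_HOM_FRACTION,
              stream=None) -> list[tuple[str, bool, str]]:
    """Fast built-in sanity harness; returns (check, passed, detail) rows.

    Runs a small planted-truth simulation through the full calling path and
    checks marker recovery, filter flagging, SSR recovery, the shared
    rounding arithmetic and manifest determinism.
    """
    import tempfile

    checks: list[tuple[str, bool, str]] = []
    sim = SimConfig(n_genes=12, seed=seed, error_rate=0.0)
    truth = simulate_truth(sim)
    reads = simulate_reads(truth, sim)
    alignments = []
    for g, lst in reads.items():
        alignments.extend(naive_map(lst, truth.contigs, g))
    pile = snp.build_pileup(alignments, truth.contigs,
                            genotypes=list(sim.genotype_names))
    rows = snp.genotype_rows(pile, truth.contigs, hom_fraction=hom_fraction)
    candidates, het_track = snp.call_iga_snps(rows)
    kept, flagged = snp.filter_iga_snps(candidates, het_track, truth.junctions)

    clean = {(v.contig_id, v.pos) for v in truth.snps(kinds=("clean",))}
    kept_set = {(s.contig_id, s.pos) for s in kept}
    checks.append(("clean SNP recovery (recall & precision)",
                   kept_set == clean,
                   f"kept={len(kept_set)} planted_clean={len(clean)}"))
    het_near = {(v.contig_id, v.pos) for v in truth.snps(kinds=("near_het",))}
    het_flag_ok = all(
        "adjacent_het" in s.filter_flags
        for s in flagged if (s.contig_id, s.pos) in het_near)
    het_all_rejected = not (het_near & kept_set)
    checks.append(("SNPs near heterozygous sites flagged, never kept",
                   het_flag_ok and het_all_rejected,
                   f"n_near_het={len(het_near)}"))
    checks.append(("candidate partition: kept + flagged",
                   len(candidates) == len(kept) + len(flagged),
                   f"{len(candidates)} = {len(kept)} + {len(flagged)}"))

    found = set()
    for contig in truth.contigs:
        for r in ssr.find_perfect_ssrs(contig.sequence, contig_id=contig.id):
            found.add((r.contig_id, r.start, r.motif, r.repeat_count))
    planted = {(s.contig_id, s.start, s.motif, s.count) for s in truth.ssrs}
    checks.append(("planted SSR recovery", planted <= found,
                   f"planted={len(planted)} found={len(found)}"))

    checks.append(("density arithmetic",
                   stats_mod.snp_density(11_847_000, 4_234).bases_per_marker == 2798
                   and stats_mod.snp_density(76_952_000, 30_495).bases_per_marker == 2523,
                   "bases-per-marker rounding"))
    checks.append(("percentage arithmetic",
                   stats_mod.rate_pct(113, 126, 1) == 89.7
                   and stats_mod.rate_pct(22_548, 22_863, 1) == 98.6,
                   "half-up percent rounding"))

    with tempfile.TemporaryDirectory() as d1, tempfile.TemporaryDirectory() as d2:
        cfg1 = RunConfig(seed=seed, out_dir=d1,
                         sim=dataclasses.replace(sim, n_genes=4))
        cfg2 = RunConfig(seed=seed, out_dir=d2,
                         sim=dataclasses.replace(sim, n_genes=4))
        m1, m2 = run_pipeline(cfg1), run_pipeline(cfg2)
        checks.append(("manifest determinism for identical seeds",
                       json.dumps(m1, sort_keys=True, default=str)
                       == json.dumps(m2, sort_keys=True, default=str), ""))

    stream = stream or sys.stderr
    width = max(len(c[0]) for c in checks) + 2
    for name, ok, detail in checks:
        print(f"{name:<{width}} {'PASS' if ok else 'FAIL'}  {detail}",
              file=stream)
    return checks
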