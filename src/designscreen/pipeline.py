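"""End-to-end orchestration of the screening analysis.

Runs the stages in dependency order from a single seeded configuration:
synthesize the ground truth, sample and select the designed library,
simulate selection counts and reads, quality-control the reads back into a
count table, compute profile statistics, train the read-count surrogate and
measure enrichment over naive NNK libraries, and rescore a structural
ensemble. Every stage writes its artifacts into one run directory; a JSON
summary aggregates the headline numbers. Identical configuration and seed
give an identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import library, readqc, seqstats, structscore, surrogate, synthetic

__all__ = ["RunConfig", "DependencyError", "STAGES", "run", "report"]

log = logging.getLogger("designscreen")

STAGES = ("synth", "library", "screen", "qc", "stats", "surrogate", "struct")


class DependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    Defaults mirror the screening protocol the pipeline emulates (18-residue
    window starting at residue 54, top-2000-per-strategy selection budget,
    NNK naive libraries with 70% wild-type bias, Phred-30 read filter,
    per-variant count minima of 2 for phage and 5 for Y2H, a 100-forest
    surrogate with node size 3 and 7 variables per split, and a 5 A
    interface shell) — scaled down where a full-size run would be wasteful
    for a demonstration (library and naive-set sizes, forest count).
    """

    seed: int = 1
    out_dir: str = "runs/demo"
    # landscape
    window_start: int = 54
    window_length: int = 18
    n_hotspots: int = 3
    effect_size: float = 2.0
    # library design
    strategies: list[str] = field(default_factory=lambda: ["MD", "CONCOORD", "Backrub"])
    n_per_strategy: int = 2000
    k_per_strategy: int = 200
    sampling_temperature: float = 1.0
    # screening simulation
    rounds: int = 4
    depth: int = 50_000
    error_rate: float = 0.002
    # read QC
    min_phred: int = 30
    n_exempt: int = 0
    exempt_min: int = 20
    min_count: int = readqc.PHAGE_MIN_COUNT
    # surrogate
    n_surrogate_models: int = 25
    n_trees: int = 50
    grid_node_sizes: list[int] = field(default_factory=lambda: [3])
    grid_vars_per_split: list[int] = field(default_factory=lambda: [7])
    threshold: float | None = None  # None: calibrate on the best positive
    default_threshold: float = 0.6125
    # naive NNK libraries
    nnk_bias: float = 0.70
    nnk_n_sequences: int = 20_000
    nnk_replicates: int = 3
    # structures
    n_struct_models: int = 25
    displacement_sd: float = 0.5
    contact_cutoff: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _require(run_dir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (run_dir / name).exists():
            raise DependencyError(
                f"stage {stage!r} requires missing artifact {name!r}; "
                "run its upstream stage first"
            )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the selected stages (default: all) into the run directory."""
    todo = list(STAGES) if stages is None else list(stages)
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    summary_path = run_dir / "summary.json"
    summary: dict = {}
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())

    gt = synthetic.make_ground_truth(
        seed=config.seed,
        n_hotspots=config.n_hotspots,
        effect_size=config.effect_size,
        window_start=config.window_start,
        window_length=config.window_length,
    )

    if "synth" in todo:
        log.info("stage synth: ground-truth landscape")
        _write_json(
            run_dir / "ground_truth.json",
            {
                "window_start": gt.window_start,
                "window_length": gt.window_length,
                "wt_aa": gt.wt_aa,
                "hotspots": [[p, a, e] for p, a, e in gt.hotspots],
                "wt_affinity": gt.affinity(gt.wt_aa),
            },
        )
        summary["synth"] = {"wt_affinity": round(gt.affinity(gt.wt_aa), 6)}

    if "library" in todo:
        log.info("stage library: candidates + top-K selection")
        _require(run_dir, "library", "ground_truth.json")
        candidates = synthetic.simulate_design_candidates(
            gt,
            config.strategies,
            config.n_per_strategy,
            bias=config.sampling_temperature,
            seed=config.seed + 1,
        )
        library.write_candidates_tsv(candidates, str(run_dir / "candidates.tsv"))
        selected = library.select_top_candidates(candidates, config.k_per_strategy)
        library.write_candidates_tsv(selected, str(run_dir / "selected.tsv"))
        library.write_variants_fasta(selected, str(run_dir / "selected.fasta"))
        with open(run_dir / "oligos.fasta", "w") as fh:
            for rec in selected:
                fh.write(f">{rec.id}\n{library.reverse_translate(rec.window_seq)}\n")
        summary["library"] = {
            "n_candidates": len(candidates),
            "n_selected": len(selected),
            "n_unique": len({r.window_seq for r in selected}),
            "landscape_size": str(library.landscape_size(config.window_length, 20)),
        }

    if "screen" in todo:
        log.info("stage screen: selection counts + reads")
        _require(run_dir, "screen", "selected.tsv")
        selected = library.read_candidates_tsv(str(run_dir / "selected.tsv"))
        table = synthetic.simulate_selection_counts(
            selected, gt, rounds=config.rounds, depth=config.depth, seed=config.seed + 2
        )
        table.to_tsv(str(run_dir / "counts_true.tsv"))
        oligos = {r.window_seq: library.reverse_translate(r.window_seq) for r in selected}
        reads = synthetic.simulate_reads(
            table, oligos, error_rate=config.error_rate, seed=config.seed + 3
        )
        from Bio import SeqIO

        with open(run_dir / "reads.fastq", "w") as fh:
            SeqIO.write(reads, fh, "fastq")
        summary["screen"] = {
            "n_reads": len(reads),
            "n_variants_counted": int(len(table.counts(table.channels[0]))),
        }

    if "qc" in todo:
        log.info("stage qc: filter, extract, tally")
        _require(run_dir, "qc", "reads.fastq")
        with open(run_dir / "reads.fastq") as fh:
            reads = list(readqc.parse_fastq(fh))
        passing, tally = readqc.filter_reads(
            reads,
            min_phred=config.min_phred,
            n_exempt=config.n_exempt,
            exempt_min=config.exempt_min,
        )
        windows = []
        categories = {"ok": 0, "anchor": 0, "length": 0, "stop": 0, "ambiguous": 0}
        for rec in passing:
            window, cat = readqc.extract_variant_window(str(rec.seq))
            categories[cat] += 1
            if window is not None:
                windows.append(window)
        channel = f"phage_r{config.rounds}"
        qc_table, dropped = readqc.tally_variants(windows, channel, config.min_count)
        qc_table.to_tsv(str(run_dir / "counts_qc.tsv"))
        _write_json(
            run_dir / "qc_tally.json",
            {"filter": tally, "extract": categories, "n_dropped_variants": len(dropped)},
        )
        summary["qc"] = {
            "reads_in": len(reads),
            "reads_pass_quality": tally["pass"],
            "windows_recovered": categories["ok"],
            "variants_retained": int(len(qc_table.counts(channel))),
        }

    if "stats" in todo:
        log.info("stage stats: profiles, IC, JSD, divergence")
        _require(run_dir, "stats", "selected.tsv")
        selected = library.read_candidates_tsv(str(run_dir / "selected.tsv"))
        by_strategy: dict[str, list[str]] = {}
        for rec in selected:
            by_strategy.setdefault(rec.strategy, []).append(rec.window_seq)
        profiles = {s: seqstats.build_profile(seqs) for s, seqs in by_strategy.items()}
        stats_block: dict = {"divergence_from_wt_pct": {}, "mean_jsd_bits": {}}
        for s, seqs in by_strategy.items():
            np.savetxt(
                run_dir / f"profile_{s}.tsv",
                profiles[s].matrix,
                delimiter="\t",
                header="\t".join(seqstats.AA_ALPHABET),
                comments="",
            )
            stats_block["divergence_from_wt_pct"][s] = round(
                seqstats.divergence_from_reference(seqs, gt.wt_aa), 3
            )
        labels = sorted(profiles)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                _, mean_jsd = seqstats.js_divergence(profiles[a], profiles[b])
                stats_block["mean_jsd_bits"][f"{a}|{b}"] = round(mean_jsd, 4)
        _write_json(run_dir / "seqstats.json", stats_block)
        summary["stats"] = stats_block

    if "surrogate" in todo:
        log.info("stage surrogate: train, calibrate, enrich")
        _require(run_dir, "surrogate", "counts_qc.tsv", "selected.tsv")
        qc_table = readqc.ReadCountTable.from_tsv(str(run_dir / "counts_qc.tsv"))
        channel = qc_table.channels[0]
        counts = qc_table.counts(channel)
        positives = [(seq, float(c)) for seq, c in counts.items()]
        ens = surrogate.train(
            positives,
            n_models=config.n_surrogate_models,
            grid=(tuple(config.grid_node_sizes), tuple(config.grid_vars_per_split)),
            seed=config.seed + 4,
            n_trees=config.n_trees,
        )
        if config.threshold is not None:
            ens.threshold = config.threshold
        else:
            reference = counts.idxmax()  # most-enriched variant as tight binder
            surrogate.calibrate_threshold(ens, str(reference))
        selected = library.read_candidates_tsv(str(run_dir / "selected.tsv"))
        designed = {}
        for rec in selected:
            designed.setdefault(rec.strategy, []).append(rec.window_seq)
        wt_nt = library.reverse_translate(gt.wt_aa)
        spec = library.NaiveLibrarySpec(
            wt_nt=wt_nt,
            wt_bias=config.nnk_bias,
            n_sequences=config.nnk_n_sequences,
            n_replicates=config.nnk_replicates,
        )
        naive = library.simulate_nnk_library(spec, seed=config.seed + 5)
        report_ = surrogate.enrichment(ens, designed, naive)
        enrich_json = {
            "threshold": report_.threshold,
            "designed_hit_fractions": report_.designed_fractions,
            "naive_hit_fractions": list(report_.naive_fractions),
            "enrichment": {
                k: (None if np.isinf(v) else round(v, 3))
                for k, v in report_.enrichment.items()
            },
            "naive_sd": report_.naive_sd,
            "infinite": report_.infinite,
            "cv_table": {f"{ns},{mt}": round(v, 4) for (ns, mt), v in ens.cv_table.items()},
            "node_size": ens.node_size,
            "vars_per_split": ens.vars_per_split,
        }
        _write_json(run_dir / "enrichment.json", enrich_json)
        summary["surrogate"] = enrich_json

    if "struct" in todo:
        log.info("stage struct: ensemble RMSD, PCA, LJ rescoring")
        models = synthetic.simulate_structures(
            config.n_struct_models,
            n_residues=config.window_length,
            displacement_sd=config.displacement_sd,
            seed=config.seed + 6,
        )
        ref = models[0]
        (run_dir / "reference.pdb").write_text(structscore.write_pdb(ref))
        rmsds, median = structscore.ensemble_rmsd_summary(models[1:], ref)
        np.savetxt(run_dir / "rmsd.tsv", np.array(rmsds), delimiter="\t", header="rmsd")
        pca_res = structscore.backbone_pca(models, [])
        designed_positions = list(range(1, config.window_length + 1))
        lj_totals = []
        for m in models:
            contacts = structscore.interface_contacts(
                m, designed_positions, partner_chain="B", cutoff=config.contact_cutoff
            )
            if contacts:
                score = structscore.lj_interface_score(m, contacts, partner_chain="B")
                lj_totals.append(score.total)
            else:
                lj_totals.append(0.0)
        summary["struct"] = {
            "median_rmsd": round(median, 4),
            "pca_variance_fractions": [round(float(v), 4) for v in pca_res.variance_fractions],
            "lj_total_reference": round(lj_totals[0], 4),
            "lj_total_mean": round(float(np.mean(lj_totals)), 4),
        }

    _write_json(summary_path, summary)
    return run_dir


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run; never mutates artifacts."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        missing = [s for s in STAGES]
        raise FileNotFoundError(
            f"no summary.json in {run_dir}; expected outputs of stages {missing}"
        )
    summary = json.loads(summary_path.read_text())
    missing = [s for s in STAGES if s not in summary]
    lines = [f"designscreen run: {run_dir}"]
    if missing:
        lines.append(f"incomplete run; missing stages: {', '.join(missing)}")
    for stage in STAGES:
        if stage not in summary:
            continue
        lines.append(f"\n[{stage}]")
        for key, value in summary[stage].items():
            lines.append(f"  {key}: {value}")
    return "\n".join(lines) + "\n"
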