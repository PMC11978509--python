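"""End-to-end orchestration: configuration validation and the staged
synthetic (or file-based) comparison run.

Stage order: simulate -> classify -> quantify -> majors -> {coverage,
diversity, fragmentation-experiment, events, spike-in}. Every tabular
output carries a provenance header (version, seed, config hash) and the
run finishes with a machine-readable JSON summary. All thresholds default
to the study's fixed constants: 30 CPM gate for the gene-coverage ratio,
1 CPM expressed gate, 150-bp fragments, 20 background repetitions and the
top-1,000 diversity cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import read_gtf, write_gtf
from .classify import build_read_classes, unique_assignment_stats
from .coverage import (
    binned_profile,
    diversity_curve,
    gene_coverage_ratio,
    median_curve,
    top_k_fraction,
    transcript_coverage,
)
from .events import background_event_distribution, compare_transcripts, EVENT_NAMES
from .fragmentation import FragmentationParams, fragmentation_experiment
from .io import provenance_header, read_alignment_tsv, write_alignment_tsv
from .isoforms import categorize, concordance, majors_from_matrix
from .quantify import ExpressionMatrix, cpm, em_quantify, gene_expression, log2_transform
from .simulate import (
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    generate_expression,
    generate_spikein,
    simulate_long_reads,
    simulate_short_reads,
)
from .spikein import SpikeInMix, protocol_comparison

__all__ = ["RunConfig", "validate_config", "run_pipeline", "quantify_sample"]

DEFAULT_STAGES = (
    "simulate",
    "classify",
    "quantify",
    "majors",
    "coverage",
    "diversity",
    "fragmentation",
    "events",
    "spikein",
)


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    simulation: SimulationConfig | None = None
    input_annotation: Path | None = None
    input_alignments: dict[str, Path] = field(default_factory=dict)
    lr_protocol: str = "dcDNA-like"
    n_lr_replicates: int = 3
    n_sr_replicates: int = 3
    n_sr_reads: int | None = None
    stages: tuple[str, ...] = DEFAULT_STAGES
    expression_gate_cpm: float = 30.0
    expressed_gate_cpm: float = 1.0
    fragment_length: int = 150
    n_background_rep: int = 20
    top_k: int = 1000
    spike_fraction: float = 0.01


def validate_config(raw: dict) -> RunConfig:
    """Normalise a raw configuration mapping into a RunConfig.

    Missing required keys are reported all at once; a config providing
    both an input block and a simulation block is rejected; unknown keys
    produce a warning but are preserved in the error-free path.
    """
    missing = [k for k in ("seed", "outdir") if k not in raw]
    if missing:
        raise ValueError(f"missing required config keys: {missing}")
    has_input = "input" in raw
    has_sim = "simulation" in raw
    if has_input and has_sim:
        raise ValueError("config provides both input and simulation blocks")
    known = {
        "seed", "outdir", "input", "simulation", "lr_protocol",
        "n_lr_replicates", "n_sr_replicates", "n_sr_reads", "stages",
        "expression_gate_cpm", "expressed_gate_cpm", "fragment_length",
        "n_background_rep", "top_k", "spike_fraction",
    }
    for key in raw:
        if key not in known:
            warnings.warn(f"unknown config key {key!r} preserved but ignored")

    kwargs: dict = {"seed": int(raw["seed"]), "outdir": Path(raw["outdir"])}
    if has_sim:
        sim = dict(raw["simulation"])
        sim.setdefault("seed", kwargs["seed"])
        kwargs["simulation"] = SimulationConfig(**sim)
    else:
        block = raw.get("input", {})
        miss = [k for k in ("annotation",) if k not in block]
        if miss:
            raise ValueError(f"missing required input keys: {miss}")
        kwargs["input_annotation"] = Path(block["annotation"])
        kwargs["input_alignments"] = {
            k: Path(v) for k, v in block.get("alignments", {}).items()
        }
        for p in [kwargs["input_annotation"], *kwargs["input_alignments"].values()]:
            if not p.exists():
                raise ValueError(f"input path does not exist: {p}")
    for key in known - {"seed", "outdir", "input", "simulation", "stages"}:
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    return RunConfig(**kwargs)


def quantify_sample(
    reads, annotation, fragment_mode: bool = False, fragment_length: int = 150
) -> pd.Series:
    """Classify a read population and run the EM; fragment mode applies the
    effective-length correction (length - fragment length + 1)."""
    classes = build_read_classes(reads, annotation)
    eff = None
    if fragment_mode:
        eff = pd.Series(
            {t.id: max(t.length - fragment_length + 1, 1)
             for t in annotation.transcripts.values()}
        )
    return em_quantify(
        classes, transcripts=sorted(annotation.transcripts), effective_lengths=eff
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(cfg.seed, {"outdir": str(cfg.outdir)}))
        df.to_csv(fh, sep="\t")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the staged comparison; returns the machine-readable summary.

    A stage failure aborts only the stages that depend on it; partial
    results stay on disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": {}}
    enabled = set(cfg.stages)

    # --- simulate / load ---------------------------------------------------
    if cfg.simulation is not None:
        sim = cfg.simulation
        annotation, seqs = generate_annotation(sim)
        n_samples = cfg.n_lr_replicates + cfg.n_sr_replicates
        truth = generate_expression(annotation, sim, n_samples)
        if "simulate" in enabled:
            write_gtf(annotation, out / "annotation.gtf")
            with open(out / "transcripts.fa", "w") as fh:
                for tid, seq in seqs.items():
                    fh.write(f">{tid}\n{seq}\n")
            _write_tsv(truth.cpm, out / "truth_cpm.tsv", cfg)
        lr_samples = {
            f"LR{r}": simulate_long_reads(
                truth.cpm.iloc[:, r], annotation, cfg.lr_protocol,
                sim.n_reads, sim.seed, sample_index=r,
            )
            for r in range(cfg.n_lr_replicates)
        }
        n_sr = cfg.n_sr_reads or sim.n_reads
        sr_samples = {
            f"SR{r}": simulate_short_reads(
                truth.cpm.iloc[:, cfg.n_lr_replicates + r], annotation,
                n_sr, sim.seed, fragment_length=cfg.fragment_length,
                sample_index=r,
            )
            for r in range(cfg.n_sr_replicates)
        }
        summary["stages"]["simulate"] = {
            "n_genes": len(annotation.genes),
            "n_transcripts": len(annotation.transcripts),
            "n_lr_samples": len(lr_samples),
            "n_sr_samples": len(sr_samples),
        }
    else:
        annotation = read_gtf(cfg.input_annotation)
        seqs = {}
        truth = None
        lr_samples = {
            name: read_alignment_tsv(path)
            for name, path in cfg.input_alignments.items()
        }
        sr_samples = {}

    samples = {**lr_samples, **sr_samples}

    # --- classify ----------------------------------------------------------
    classes_by_sample = {}
    if "classify" in enabled:
        rows = []
        for name, reads in samples.items():
            classes = build_read_classes(reads, annotation)
            classes_by_sample[name] = classes
            hist, unique_frac = unique_assignment_stats(classes)
            n_fsm = sum(c.count for c in classes if c.label == "full_splice_match")
            n_total = sum(c.count for c in classes)
            rows.append(
                {
                    "sample": name,
                    "n_assigned": n_total,
                    "fsm_fraction": n_fsm / n_total if n_total else np.nan,
                    "unique_fraction": unique_frac,
                }
            )
        cls_df = pd.DataFrame(rows).set_index("sample")
        _write_tsv(cls_df, out / "classification.tsv", cfg)
        summary["stages"]["classify"] = cls_df.to_dict(orient="index")

    # --- quantify ----------------------------------------------------------
    lr_cpm = sr_cpm = None
    if "quantify" in enabled and classes_by_sample:
        eff = pd.Series(
            {t.id: max(t.length - cfg.fragment_length + 1, 1)
             for t in annotation.transcripts.values()}
        )
        cols = {}
        for name in samples:
            frag_mode = name in sr_samples
            counts = em_quantify(
                classes_by_sample[name],
                transcripts=sorted(annotation.transcripts),
                effective_lengths=eff if frag_mode else None,
            )
            cols[name] = cpm(counts)
        mat = pd.DataFrame(cols)
        meta = pd.DataFrame(
            {
                "cell_line": "synthetic",
                "protocol": ["LR" if s in lr_samples else "SR" for s in mat.columns],
                "replicate": [s[2:] for s in mat.columns],
            },
            index=mat.columns,
        )
        ExpressionMatrix(mat, meta).to_tsv(out / "transcript_cpm.tsv")
        _write_tsv(gene_expression(mat, annotation), out / "gene_cpm.tsv", cfg)
        lr_cpm = mat[[s for s in mat.columns if s in lr_samples]]
        sr_cpm = mat[[s for s in mat.columns if s in sr_samples]]
        summary["stages"]["quantify"] = {"n_transcripts": int(mat.shape[0])}

    # --- majors ------------------------------------------------------------
    tx_table = None
    if "majors" in enabled and lr_cpm is not None and not sr_cpm.empty:
        lr_major = majors_from_matrix(lr_cpm, annotation)
        sr_major = majors_from_matrix(sr_cpm, annotation)
        tx_table, gene_table = categorize(lr_major, sr_major, annotation)
        n_agree, n_disagree = concordance(gene_table)
        _write_tsv(gene_table, out / "major_isoforms.tsv", cfg)
        _write_tsv(tx_table, out / "transcript_categories.tsv", cfg)
        summary["stages"]["majors"] = {
            "n_agree": n_agree,
            "n_disagree": n_disagree,
            "n_excluded": gene_table.attrs["n_excluded"],
        }

    # --- coverage ----------------------------------------------------------
    if "coverage" in enabled and samples:
        name, reads = next(iter(lr_samples.items() if lr_samples else samples.items()))
        by_tx: dict[str, list] = {}
        for r in reads:
            by_tx.setdefault(r.target, []).append(r)
        profiles = []
        for tid, alns in by_tx.items():
            depth = transcript_coverage(alns, annotation.transcripts[tid].length)
            prof = binned_profile(depth, tid, len(alns))
            if prof is not None:
                profiles.append(prof.bins)
        if profiles:
            mean_prof = np.mean(np.vstack(profiles), axis=0)
            pd.DataFrame({"bin": np.arange(1, 101), "mean_coverage": mean_prof}).to_csv(
                out / "coverage_profile.tsv", sep="\t", index=False
            )
            summary["stages"]["coverage"] = {
                "sample": name,
                "n_profiled_transcripts": len(profiles),
                "three_prime_mean": float(mean_prof[-20:].mean()),
                "five_prime_mean": float(mean_prof[:20].mean()),
            }

    # --- diversity ---------------------------------------------------------
    if "diversity" in enabled and lr_cpm is not None:
        gene_mat = gene_expression(pd.concat([lr_cpm, sr_cpm], axis=1), annotation)
        curves = {
            s: diversity_curve(gene_mat[s]) for s in gene_mat.columns
        }
        med = median_curve(list(curves.values()))
        pd.DataFrame({"rank": np.arange(1, len(med) + 1), "cumulative_fraction": med}).to_csv(
            out / "diversity_curve.tsv", sep="\t", index=False
        )
        summary["stages"]["diversity"] = {
            "top_k": cfg.top_k,
            "median_top_k_fraction": top_k_fraction(med, cfg.top_k),
        }

    # --- fragmentation experiment ------------------------------------------
    if "fragmentation" in enabled and tx_table is not None and lr_samples:
        name, reads = next(iter(lr_samples.items()))
        params = FragmentationParams(L=cfg.fragment_length, seed=cfg.seed)
        sr_ref = sr_cpm.mean(axis=1) if sr_cpm is not None and not sr_cpm.empty else None
        res = fragmentation_experiment(
            reads, annotation, tx_table, params, short_read_cpm=sr_ref
        )
        frame = pd.DataFrame(
            {
                "spearman": res["spearman_by_category"],
                "mae": res["mae_by_category"],
            }
        )
        _write_tsv(frame, out / "fragmentation_agreement.tsv", cfg)
        summary["stages"]["fragmentation"] = {
            "sample": name,
            "n_fragments": res["n_fragments"],
            "spearman_by_category": res["spearman_by_category"].to_dict(),
            "spearman_sr_vs_original": res.get("spearman_sr_vs_original"),
            "spearman_sr_vs_fragmented": res.get("spearman_sr_vs_fragmented"),
        }

    # --- events ------------------------------------------------------------
    if "events" in enabled and tx_table is not None:
        gene_table = pd.read_csv(
            out / "major_isoforms.tsv", sep="\t", comment="#", index_col=0
        )
        disagree = gene_table[~gene_table["agree"].astype(bool)]
        obs = np.zeros(len(EVENT_NAMES))
        pairs = []
        for gid, row in disagree.iterrows():
            ev = compare_transcripts(
                annotation.transcripts[row["sr_major"]],
                annotation.transcripts[row["lr_major"]],
            )
            obs += np.array(
                [ev.as_dict()[name] for name in EVENT_NAMES], dtype=float
            )
            pairs.append((gid, row["lr_major"]))
        if pairs:
            obs_frac = obs / len(pairs)
            bg = background_event_distribution(
                pairs, annotation, n_rep=cfg.n_background_rep,
                seed=cfg.seed,
            )
            table = bg.copy()
            table.insert(0, "observed", obs_frac)
            _write_tsv(table, out / "event_comparison.tsv", cfg)
            summary["stages"]["events"] = {
                "n_gene_pairs": len(pairs),
                "observed": dict(zip(EVENT_NAMES, obs_frac)),
                "background_mean": bg["mean"].to_dict(),
            }

    # --- spike-in ----------------------------------------------------------
    if "spikein" in enabled and cfg.simulation is not None:
        tids = sorted(annotation.transcripts)[:8]
        rng = np.random.default_rng(cfg.seed)
        rel = rng.dirichlet(np.ones(len(tids)))
        mix_design = dict(zip(tids, rel / rel.sum()))
        lengths = {t: annotation.transcripts[t].length for t in tids}
        spike_reads, sheet = generate_spikein(
            mix_design, cfg.spike_fraction, cfg.simulation.n_reads, cfg.seed, lengths
        )
        sheet.to_csv(out / "spikein_sheet.csv", index=False)
        counts = quantify_sample(spike_reads, annotation)
        est = cpm(counts + 1e-12) * cfg.spike_fraction  # pooled spike-only sample
        mixes = {
            "synthetic-mix": SpikeInMix(
                "synthetic-mix",
                pd.Series(mix_design),
                sheet.set_index("transcript_id")["gene_id"],
            )
        }
        table = protocol_comparison(
            {cfg.lr_protocol: est}, mixes, cfg.spike_fraction
        )
        table.to_csv(out / "spikein_metrics.tsv", sep="\t", index=False)
        summary["stages"]["spikein"] = table.iloc[0][
            ["spearman", "mae", "rmse"]
        ].to_dict()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
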