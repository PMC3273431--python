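"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis flow: domain scan -> functional annotation
-> tree -> selection -> expression.  Every stage writes a JSON artifact into
the output directory and contributes counts to a run report.  All
randomness flows from explicit seeds in the configuration.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import expression as expr_mod
from . import functional_sites, kunitz_domains, phylo, selection
from .codon import thread_codon_alignment
from .io_formats import (
    read_est_counts,
    read_fasta,
    read_nucleotide_fasta,
)
from .tree import parse_newick

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("kunitzkit")

STAGES = ("scan", "annotate", "tree", "selection", "express")

_LRT_PAIRS = (("M0", "M3", 4), ("M1a", "M2a", 2), ("M7", "M8", 2))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str
    stages: tuple[str, ...] = STAGES
    proteins: str | None = None  # unaligned protein FASTA (scan/annotate)
    alignment: str | None = None  # aligned protein FASTA (tree/selection)
    cds: str | None = None  # in-frame CDS FASTA (selection)
    counts: str | None = None  # EST count TSV (express)
    tree_file: str | None = None  # newick (selection, if no tree stage)
    tolerance: int = 2
    max_l1: int = 3
    window: int = 6
    r_min: float = 9.0
    b_min: float = 99.0
    n_sim: int = 1000
    distance_model: str = "poisson"
    bootstrap: int = 0
    models: tuple[str, ...] = ("M0", "M1a", "M2a")
    freq_scheme: str = "F3x4"
    n_restarts: int = 3
    posterior_method: str = "BEB"
    seed: int | None = None

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "models"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        needed = {
            "scan": [self.proteins],
            "annotate": [self.proteins],
            "tree": [self.alignment],
            "selection": [self.alignment, self.cds],
            "express": [self.counts],
        }
        for stage in self.stages:
            for path in needed[stage]:
                if path is None:
                    raise ValueError(f"stage {stage!r} needs an input path")
                if not Path(path).exists():
                    raise FileNotFoundError(f"stage {stage!r}: missing input {path}")
        stochastic = ("express" in self.stages or
                      ("tree" in self.stages and self.bootstrap > 0) or
                      "selection" in self.stages)
        if stochastic and self.seed is None:
            raise ValueError("a seed is required when a stochastic stage is enabled")


def _domain_json(dom: kunitz_domains.KunitzDomain) -> dict:
    return {
        "cys_positions_1based": [p + 1 for p in dom.cys_positions],
        "spacing": list(dom.spacing),
        "group": dom.group,
        "exact_match": dom.exact_match,
        "segment_start_1based": dom.segment_start + 1,
        "segment_end_1based": dom.segment_end,  # inclusive in 1-based terms
    }


def _write_json(outdir: Path, name: str, payload) -> None:
    path = outdir / name
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote %s", path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    started = time.perf_counter()
    scans: dict | None = None
    tree_obj = None

    for stage in [s for s in STAGES if s in config.stages]:
        t0 = time.perf_counter()
        log.info("running stage %s", stage)
        try:
            if stage == "scan":
                records = read_fasta(config.proteins)
                ids = [r.id for r in records]
                if len(set(ids)) != len(ids):
                    raise ValueError("duplicate protein ids in input FASTA")
                scans = {
                    rec.id: (rec, kunitz_domains.scan_record(
                        rec, tolerance=config.tolerance, max_l1=config.max_l1))
                    for rec in records
                }
                payload = {}
                tallies: dict[str, int] = {}
                groups: dict[str, int] = {}
                for rec_id, (rec, doms) in scans.items():
                    arch = kunitz_domains.architecture(rec, doms)
                    payload[rec_id] = {
                        "architecture": arch.label,
                        "domains": [_domain_json(d) for d in doms],
                    }
                    tallies[arch.label] = tallies.get(arch.label, 0) + 1
                    for d in doms:
                        groups[d.group] = groups.get(d.group, 0) + 1
                _write_json(outdir, "domains.json", payload)
                report["stages"]["scan"] = {
                    "proteins": len(scans),
                    "domains": sum(len(d) for _, d in scans.values()),
                    "architectures": tallies,
                    "groups": groups,
                }
            elif stage == "annotate":
                if scans is None:
                    records = read_fasta(config.proteins)
                    scans = {
                        rec.id: (rec, kunitz_domains.scan_record(
                            rec, tolerance=config.tolerance, max_l1=config.max_l1))
                        for rec in records
                    }
                payload = {}
                n_trypsin = n_channel = 0
                for rec_id, (rec, doms) in scans.items():
                    anns = []
                    for d in doms:
                        ann = functional_sites.annotate_domain(
                            d, rec, window=config.window)
                        n_trypsin += ann.inhibitor_class == "trypsin"
                        n_channel += ann.channel_modulator
                        anns.append({
                            "p1_position_1based": ann.p1_position + 1,
                            "p1_residue": ann.p1_residue,
                            "inhibitor_class": ann.inhibitor_class,
                            "channel_modulator": ann.channel_modulator,
                            "channel_evidence_1based": (
                                [ann.channel_evidence[0] + 1,
                                 ann.channel_evidence[1] + 1]
                                if ann.channel_evidence else None),
                        })
                    payload[rec_id] = anns
                _write_json(outdir, "annotations.json", payload)
                report["stages"]["annotate"] = {
                    "domains": sum(len(v) for v in payload.values()),
                    "trypsin_inhibitors": n_trypsin,
                    "channel_modulators": n_channel,
                }
            elif stage == "tree":
                aln = read_fasta(config.alignment)
                if config.bootstrap > 0:
                    tree_obj = phylo.bootstrap_support(
                        aln, n_reps=config.bootstrap, seed=config.seed or 0,
                        model=config.distance_model)
                else:
                    tree_obj = phylo.neighbor_joining(
                        phylo.protein_distance(aln, model=config.distance_model))
                newick = tree_obj.newick(support_as_label=config.bootstrap > 0)
                (outdir / "tree.nwk").write_text(newick + "\n", encoding="utf-8")
                report["stages"]["tree"] = {
                    "taxa": tree_obj.n_leaves(),
                    "bootstrap_replicates": config.bootstrap,
                }
            elif stage == "selection":
                aln = read_fasta(config.alignment)
                cds = read_nucleotide_fasta(config.cds)
                codon_aln = thread_codon_alignment(aln, cds)
                if tree_obj is None:
                    if config.tree_file:
                        tree_obj = parse_newick(
                            Path(config.tree_file).read_text(encoding="utf-8"))
                    else:
                        tree_obj = phylo.neighbor_joining(
                            phylo.protein_distance(aln, model=config.distance_model))
                fits = selection.fit_models(
                    codon_aln, tree_obj, config.models,
                    freq_scheme=config.freq_scheme,
                    n_restarts=config.n_restarts, seed=config.seed or 0)
                payload = {
                    "models": {
                        name: {
                            "lnL": fit.lnL,
                            "kappa": fit.model.kappa,
                            "params": {k: (list(v) if isinstance(v, tuple) else v)
                                       for k, v in fit.model.params.items()},
                            "converged": fit.converged,
                        }
                        for name, fit in fits.items()
                    },
                    "lrt": {},
                    "positive_sites_1based": {},
                }
                n_sig = 0
                for null_name, alt_name, df in _LRT_PAIRS:
                    if null_name in fits and alt_name in fits:
                        lrt = selection.likelihood_ratio_test(
                            fits[null_name], fits[alt_name], df)
                        payload["lrt"][f"{null_name}_vs_{alt_name}"] = {
                            "two_delta_l": lrt.two_delta_l,
                            "df": lrt.df,
                            "p_value": lrt.p_value,
                            "significant_1pct": lrt.significant_1pct,
                        }
                        n_sig += lrt.significant_1pct
                        if lrt.significant_1pct and alt_name in ("M2a", "M8"):
                            post = selection.site_posteriors(
                                fits[alt_name], codon_aln,
                                method=config.posterior_method)
                            payload["positive_sites_1based"][alt_name] = [
                                s + 1 for s in post.positive_sites]
                _write_json(outdir, "selection.json", payload)
                report["stages"]["selection"] = {
                    "models": list(fits),
                    "significant_lrts": n_sig,
                    "positive_sites": {
                        m: len(v)
                        for m, v in payload["positive_sites_1based"].items()
                    },
                }
            elif stage == "express":
                matrix = read_est_counts(config.counts)
                results = expr_mod.call_differential(
                    matrix, r_min=config.r_min, b_min=config.b_min,
                    n_sim=config.n_sim, seed=config.seed or 0)
                payload = {
                    "log_base": "e",
                    "r_min": config.r_min,
                    "b_min": config.b_min,
                    "genes": [
                        {
                            "gene_id": g.gene_id,
                            "counts": list(g.counts),
                            "r": g.r_value,
                            "believability": g.believability,
                            "significant": g.significant,
                            "pattern": g.pattern,
                        }
                        for g in results
                    ],
                }
                _write_json(outdir, "expression.json", payload)
                report["stages"]["express"] = {
                    "genes": len(results),
                    "significant": sum(g.significant for g in results),
                    "patterns": {
                        p: sum(g.pattern == p for g in results)
                        for p in ("pattern1", "pattern2", "other")
                    },
                }
        except (ValueError, KeyError, FileNotFoundError) as exc:
            raise PipelineError(stage, str(exc)) from exc
        report["stages"].setdefault(stage, {})
        report["stages"][stage]["seconds"] = round(time.perf_counter() - t0, 3)

    report["wall_clock_seconds"] = round(time.perf_counter() - started, 3)
    report["config"] = asdict(config)
    _write_json(outdir, "report.json", report)
    return report
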