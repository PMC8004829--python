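"""End-to-end pipeline driver.

Runs the stages in study order — simulate (optional), translated search,
variant catalogue + PAV, peptide chemistry, cysteine-array typing,
distance tree + site selection, promoter motifs, expression screen +
concordance — and writes each stage's tables under an output directory.
Every run is fully determined by the configuration (including the RNG
seed), and each output file carries the tool version, seed and config
hash in a header comment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cysteine_arrays, peptide_chemistry, promoter_motifs
from . import expression_screen as es
from . import molecular_evolution as mev
from .io import write_fasta, write_newick, write_tsv
from .synthetic_data import SimConfig, generate_cohort
from .translated_search import ScoringScheme, recover_variants
from .variant_catalogue import build_pav, cluster_variants, flag_pseudogenes


@dataclass
class PipelineConfig:
    """Stage toggles plus every analysis threshold, in one place."""

    sim: SimConfig = field(default_factory=SimConfig)
    rng_seed: int = 0
    identity_threshold: float = 95.0  # clustering + expression evidence
    promoter_window: int = 1000
    motif_min_width: int = 6
    motif_max_width: int = 30
    n_motifs: int = 10
    sliding_window: int = 15
    alpha: float = 0.1
    min_score: float | None = None  # None -> shuffled-null calibration
    mature_coverage: float = 0.6
    stages: tuple[str, ...] = (
        "simulate", "search", "catalogue", "peptides", "cystypes",
        "evolve", "promoter", "express",
    )
    outdir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, completed: list[str]):
        super().__init__(
            f"stage '{stage}' failed: {message} (completed: {', '.join(completed) or 'none'})"
        )
        self.stage = stage
        self.completed = completed


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the summary report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    completed: list[str] = []
    report: dict = {"seed": seed}
    ctx: dict = {}

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"pipeline": _plain(config), "sim": _plain(config.sim)}, fh)

    def fail(stage, msg):
        raise StageError(stage, msg, completed)

    if "simulate" in config.stages:
        cohort = generate_cohort(config.sim)
        ctx["cohort"] = cohort
        for ind in cohort.individuals:
            write_fasta(ind.contigs, out / f"genomes/{ind.individual_id}.fa")
        for t in cohort.transcriptomes:
            write_fasta(t.transcripts, out / f"transcriptomes/{t.individual_id}.fa")
        write_tsv(cohort.manifest.to_frame(), out / "manifest.tsv",
                  seed=seed, config=config.sim)
        report["planted_copies"] = len(cohort.manifest.copies)
        completed.append("simulate")

    if "search" in config.stages:
        if "cohort" not in ctx:
            fail("search", "no genomes available; enable the simulate stage "
                           "or provide inputs programmatically")
        cohort = ctx["cohort"]
        seed_prec = cohort.panel.seed
        result = recover_variants(
            cohort.genomes, seed_prec.protein, seed_prec.annotation.mature,
            scheme=ScoringScheme(min_score=config.min_score),
            mature_coverage=config.mature_coverage,
            calibration_rng=seed,
        )
        ctx["search"] = result
        write_fasta([(v.variant_id, v.cds) for v in result.variants],
                    out / "variants_nt.fa")
        write_fasta([(v.variant_id, v.protein) for v in result.variants],
                    out / "variants_protein.fa")
        loci = pd.DataFrame(
            [
                {
                    "genome": g, "contig": m.contig_id,
                    "start": min(s for s, _ in m.exons),
                    "end": max(e for _, e in m.exons),
                    "strand": m.strand,
                    "n_exons": len(m.exons),
                    "score": m.score,
                    "partial": m.partial,
                }
                for g, ms in result.models.items()
                for m in ms
            ]
        )
        write_tsv(loci, out / "loci.tsv", seed=seed, config=config)
        report["n_variants"] = len(result.variants)
        completed.append("search")

    if "catalogue" in config.stages:
        if "search" not in ctx:
            fail("catalogue", "search stage did not run")
        variants, counts = flag_pseudogenes(ctx["search"].variants)
        clusters = cluster_variants(variants, threshold=config.identity_threshold)
        genome_ids = sorted(ctx["cohort"].genomes)
        pav = build_pav(variants, genome_ids, clusters)
        ctx.update(variants=variants, clusters=clusters, pav=pav)
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "cluster": c.label,
                        "n_members": len(c.members),
                        "members": ",".join(c.members),
                        "min_identity": c.min_identity,
                    }
                    for c in clusters
                ]
            ),
            out / "clusters.tsv", seed=seed, config=config,
        )
        write_fasta([(f"{c.label}_nt", c.nt_consensus) for c in clusters]
                    + [(f"{c.label}_protein", c.protein_consensus) for c in clusters],
                    out / "consensus.fa")
        write_tsv(pav.variant_matrix.astype(int), out / "pav_variants.tsv",
                  seed=seed, config=config, index=True)
        write_tsv(pav.cluster_matrix.astype(int), out / "pav_clusters.tsv",
                  seed=seed, config=config, index=True)
        report.update(
            n_peptides=len({v.protein for v in variants}),
            n_pseudogenes=counts["pseudogene"],
            n_functional=counts["functional"],
            n_clusters=len(clusters),
            mean_variants_per_genome=pav.mean_variants_per_genome,
            mean_unique_variants_per_genome=pav.mean_unique_variants_per_genome,
            cluster_frequencies={k: float(v) for k, v in pav.cluster_frequency.items()},
        )
        completed.append("catalogue")

    if "peptides" in config.stages:
        if "clusters" not in ctx:
            fail("peptides", "catalogue stage did not run")
        seed_prec = ctx["cohort"].panel.seed
        rows = []
        for v in ctx["variants"]:
            if v.pseudogene or v.partial:
                continue
            ann = peptide_chemistry.segment_precursor(
                v.protein, seed_prec.protein, seed_prec.annotation
            )
            mature = v.protein[ann.mature[0]:ann.mature[1]]
            pi, _ = peptide_chemistry.isoelectric_point(mature)
            rows.append(
                {
                    "variant": v.variant_id,
                    "cluster": ctx["pav"].assignment[v.variant_id],
                    "mature_start": ann.mature[0],
                    "mature_end": ann.mature[1],
                    "pI": round(pi, 3),
                    "charge_pH7.4": round(peptide_chemistry.net_charge(mature, 7.4), 3),
                    "mw": round(peptide_chemistry.molecular_weight(mature), 1),
                }
            )
        peptide_table = pd.DataFrame(rows)
        write_tsv(peptide_table, out / "peptides.tsv", seed=seed, config=config)
        profiles = []
        for c in ctx["clusters"]:
            centers, values, _ = peptide_chemistry.sliding_window_pi(
                c.protein_consensus, window=config.sliding_window
            )
            profiles.append(
                pd.DataFrame({"cluster": c.label, "center": centers, "pI": values})
            )
        write_tsv(pd.concat(profiles, ignore_index=True), out / "pi_profiles.tsv",
                  seed=seed, config=config)
        ctx["peptides"] = peptide_table
        report["n_mature_peptides"] = len(rows)
        completed.append("peptides")

    if "cystypes" in config.stages:
        if "clusters" not in ctx:
            fail("cystypes", "catalogue stage did not run")
        seed_prec = ctx["cohort"].panel.seed
        rows = []
        calls = []
        for v in ctx["variants"]:
            if v.pseudogene or v.partial:
                continue
            ann = peptide_chemistry.segment_precursor(
                v.protein, seed_prec.protein, seed_prec.annotation
            )
            mature = v.protein[ann.mature[0]:ann.mature[1]]
            call = cysteine_arrays.classify_peptide(mature)
            label = ctx["pav"].assignment[v.variant_id]
            calls.append((label, call))
            rows.append(
                {
                    "variant": v.variant_id,
                    "cluster": label,
                    "array": cysteine_arrays.fingerprint(mature).to_string(),
                    "type": call.array_type,
                    "bonds": ",".join(map(str, call.bonds)),
                    "n_cys": call.n_cys,
                }
            )
        write_tsv(pd.DataFrame(rows), out / "cys_types.tsv", seed=seed, config=config)
        occurrence = cysteine_arrays.summarize_taxa(calls)
        write_tsv(occurrence.astype(int), out / "cys_occurrence.tsv",
                  seed=seed, config=config, index=True)
        report["array_types"] = cysteine_arrays.type_membership(calls)
        completed.append("cystypes")

    if "evolve" in config.stages:
        if "clusters" not in ctx:
            fail("evolve", "catalogue stage did not run")
        functional = {
            v.variant_id: v.cds
            for v in ctx["variants"]
            if not v.pseudogene and not v.partial
        }
        if len(functional) >= 3:
            aln = mev.codon_align(functional)
            tree = mev.nj_tree(mev.p_distance(aln))
            write_newick(tree, out / "nj_tree.nwk", seed=seed)
            sites = mev.slac_sites(aln, tree, alpha=config.alpha)
            write_tsv(
                pd.DataFrame(
                    [
                        {
                            "site": r.site, "N_obs": r.n_obs, "S_obs": r.s_obs,
                            "expected_syn": r.expected_syn_proportion,
                            "p_neg": r.p_negative, "p_pos": r.p_positive,
                            "call": r.call,
                        }
                        for r in sites
                    ]
                ),
                out / "selection_sites.tsv", seed=seed, config=config,
            )
            report["selection_calls"] = {
                "negative": sum(r.call == "negative" for r in sites),
                "positive": sum(r.call == "positive" for r in sites),
                "none": sum(r.call == "none" for r in sites),
            }
        completed.append("evolve")

    if "promoter" in config.stages:
        if "cohort" not in ctx or "search" not in ctx:
            fail("promoter", "search stage did not run")
        cohort = ctx["cohort"]
        contigs = {cid: seq for ind in cohort.individuals for cid, seq in ind.contigs}
        models = [m for ms in ctx["search"].models.values() for m in ms]
        proms = promoter_motifs.extract_promoters(
            models, contigs, window=config.promoter_window
        )
        motifs = promoter_motifs.discover_motifs(
            proms,
            widths=range(config.motif_min_width, config.motif_max_width + 1),
            n_motifs=config.n_motifs,
            rng=seed,
        )
        _write_meme(motifs, out / "motifs.meme")
        presence = pd.DataFrame(
            False,
            index=[f"motif_{i+1}" for i in range(len(motifs))],
            columns=[r.label for r in proms.records],
        )
        for i, m in enumerate(motifs):
            for label, *_ in m.occurrences:
                presence.loc[f"motif_{i+1}", label] = True
        write_tsv(presence.astype(int), out / "motif_presence.tsv",
                  seed=seed, config=config, index=True)
        report["n_motifs"] = len(motifs)
        report["motif_consensus"] = [m.consensus for m in motifs]
        completed.append("promoter")

    if "express" in config.stages:
        if "clusters" not in ctx:
            fail("express", "catalogue stage did not run")
        cohort = ctx["cohort"]
        seed_prec = cohort.panel.seed
        consensus_proteins = {
            c.label: c.protein_consensus for c in ctx["clusters"]
        }
        evidence = es.screen_expression(
            consensus_proteins,
            cohort.transcript_sets,
            seed_prec.annotation.mature,
            identity_threshold=config.identity_threshold,
        )
        write_tsv(evidence.matrix.astype(int), out / "expression.tsv",
                  seed=seed, config=config, index=True)
        report["expressed_clusters"] = {
            s: sorted(evidence.matrix.index[evidence.matrix[s]])
            for s in evidence.matrix.columns
        }
        completed.append("express")

    report["completed_stages"] = completed
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(_plain_tree(report), fh, sort_keys=True)
    return report


def _plain(obj) -> dict:
    d = asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
    return {k: _plain_tree(v) for k, v in d.items()}


def _plain_tree(v):
    if isinstance(v, dict):
        return {k: _plain_tree(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_plain_tree(x) for x in v]
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if hasattr(v, "__dataclass_fields__"):
        return _plain(v)
    return v


def _write_meme(motifs, path: Path) -> None:
    """Minimal MEME-format motif text for interoperability."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write(
                "Background letter frequencies\n"
                f"A {bg[0]:.3f} C {bg[1]:.3f} G {bg[2]:.3f} T {bg[3]:.3f}\n\n"
            )
        for i, m in enumerate(motifs):
            fh.write(f"MOTIF motif_{i+1} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {max(1, round(m.site_count))} E= 0\n"
            )
            for row in m.pwm:
                fh.write(" " + "  ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
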