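"""End-to-end driver: simulation → k-mers → GWAS → fragments →
phenotype indices → root-architecture traits, with a checksummed
manifest for reproducibility.

Every stage writes its outputs as plain TSV/FASTA/GFF3 under the run
directory; identical configuration and seed yield byte-identical
outputs and therefore identical manifest checksums.  Reads are streamed
accession-by-accession and, by default, not persisted (``write_reads``
turns FASTQ output on).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, fragments as frag_mod, io as _io, kmers as kmer_mod
from . import pheno as pheno_mod, rsa as rsa_mod, simdata
from .config import RunConfig

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the failing stage."""


@dataclass
class PipelineResult:
    config: RunConfig
    outdir: Path
    paths: dict[str, Path] = field(default_factory=dict)
    reference: simdata.ReferenceGenome | None = None
    population: simdata.Population | None = None
    matrix: kmer_mod.KmerMatrix | None = None
    results: list | None = None
    tier: str = "none"
    selected: list | None = None
    fragment_list: list | None = None
    candidates: pd.DataFrame | None = None
    indices: pd.DataFrame | None = None
    groups: pd.DataFrame | None = None
    rsa_table: pd.DataFrame | None = None
    planted_gene: str | None = None
    diagnostic_neglog10p: np.ndarray | None = None
    planted_gene_recovered: bool = False
    manifest: dict = field(default_factory=dict)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def plan_loci(
    ref: simdata.ReferenceGenome, config: RunConfig, seed: int
) -> tuple[list[simdata.CausalLocus], str]:
    """Place one causal presence/absence segment near a gene, plus
    neutral segments spread along the genome for background structure.

    Returns the loci and the id of the gene expected to be recovered in
    the ±half_width candidate window around the causal locus.
    """
    rng = np.random.default_rng(seed)
    genes = ref.genes.sort_values(["contig", "start"]).reset_index(drop=True)
    gene = genes.iloc[len(genes) // 2]
    contig_len = ref.contig_lengths()[gene.contig]
    margin = config.k + 1
    start = int(gene.end) + 1_000
    if start + config.causal_length + margin > contig_len:
        start = max(margin, int(gene.start) - 1_000 - config.causal_length)
    causal = simdata.CausalLocus(
        gene.contig, start, config.causal_length, config.causal_freq,
        config.causal_beta, name="causal",
    )
    loci = [causal]
    name, seq = ref.contigs[0]
    anchors = np.linspace(
        margin, len(seq) - config.causal_length - margin, config.n_neutral_loci + 2
    )[1:-1]
    for i, pos in enumerate(anchors):
        start_i = int(pos)
        if abs(start_i - causal.start) < 2 * config.causal_length and name == causal.contig:
            start_i += 4 * config.causal_length
        loci.append(simdata.CausalLocus(
            name, start_i, config.causal_length,
            float(rng.uniform(0.1, 0.9)), 0.0, name=f"neutral{i + 1:02d}",
        ))
    return loci, str(gene.gene_id)


def _write(paths: dict[str, Path], outdir: Path, name: str, filename: str, writer) -> None:
    path = outdir / filename
    writer(path)
    paths[name] = path


def run_pipeline(config: RunConfig, outdir) -> PipelineResult:
    config.validate()
    outdir = _io.ensure_dir(outdir)
    result = PipelineResult(config=config, outdir=outdir)
    paths = result.paths
    seeds = _child_seeds(config.seed, 8)
    stage = "configure"
    try:
        if not config.simulate:
            return _run_external(config, outdir, result)

        stage = "reference"
        ref = simdata.generate_reference(
            config.n_contigs, config.contig_length, config.n_genes,
            config.gene_length, seeds[0],
        )
        result.reference = ref
        _write(paths, outdir, "reference", "reference.fa", ref.write_fasta)
        _write(paths, outdir, "genes", "genes.gff3", ref.write_gff3)

        stage = "population"
        loci, planted_gene = plan_loci(ref, config, seeds[1])
        result.planted_gene = planted_gene
        spec = simdata.PopulationSpec(
            config.n_accessions, loci, snp_rate=config.snp_rate, seed=seeds[2],
        )
        population = simdata.simulate_population(ref, spec, k=config.k)
        result.population = population
        truth = population.truth
        _write(paths, outdir, "truth", "truth.tsv",
               lambda p: truth.reset_index().to_csv(p, sep="\t", index=False))

        stage = "phenotypes"
        # polygenic background from the NEUTRAL loci only: the causal
        # effect enters through beta, so the background kinship must not
        # double-count the causal carriage direction
        neutral_cols = [l.name for l in loci if l.beta == 0.0]
        carriage = truth[neutral_cols].to_numpy(dtype=float) if neutral_cols \
            else truth.to_numpy(dtype=float)
        centred = carriage - carriage.mean(axis=0)
        K_truth = centred @ centred.T / max(carriage.shape[1], 1)
        betas = [l.beta for l in loci]
        pheno_tables = []
        sdm = simdata.simulate_phenotypes(truth, K_truth, simdata.PhenoSimParams(
            mu=config.mu, betas=betas, sigma_g2=config.sigma_g2,
            sigma_e2=config.sigma_e2, treatment_effect=config.treatment_effect,
            n_replicates=config.n_replicates, seed=seeds[3], trait="SDM",
            clip_at=0.01,
        ))
        rdm = simdata.simulate_phenotypes(truth, K_truth, simdata.PhenoSimParams(
            mu=1.43, betas=[0.0] * len(loci), sigma_g2=0.12, sigma_e2=0.05,
            treatment_effect=-0.33, n_replicates=config.n_replicates,
            seed=seeds[4], trait="RDM", clip_at=0.01,
        ))
        conc = simdata.simulate_phenotypes(truth, K_truth, simdata.PhenoSimParams(
            mu=4.2, betas=[0.0] * len(loci), sigma_g2=0.04, sigma_e2=0.09,
            treatment_effect=-1.5, n_replicates=config.n_replicates,
            seed=seeds[5], trait="shoot_P_conc", clip_at=0.1,
        ))
        pheno_table = pd.concat([sdm, rdm, conc], ignore_index=True)
        _write(paths, outdir, "phenotypes", "phenotypes.tsv",
               lambda p: _io.write_tsv(pheno_table, p))

        stage = "kmers"
        read_params = simdata.ReadSimParams(
            read_length=config.read_length, coverage=config.coverage,
            error_rate=config.error_rate, seed=seeds[6],
        )
        tally = kmer_mod.StrandTally()
        sample_codes: dict[str, np.ndarray] = {}
        reads_dir = outdir / "reads"
        if config.write_reads:
            reads_dir.mkdir(exist_ok=True)
        for acc, readset in simdata.iter_gbs_reads(population, read_params):
            if config.write_reads:
                readset.to_fastq(reads_dir / f"{acc}.fastq", prefix=acc)
            counts = kmer_mod.count_sample_kmers(
                readset, k=config.k, min_count=config.min_count,
            )
            tally.update(counts)
            sample_codes[acc] = counts.codes
        strand = tally.finalize()
        matrix = kmer_mod.build_pa_matrix(sample_codes, strand=strand, k=config.k)
        matrix = kmer_mod.filter_maf(matrix, config.maf_min)
        result.matrix = matrix
        if config.write_matrix:
            _write(paths, outdir, "kmer_matrix", "kmer_matrix.tsv", matrix.to_tsv)

        stage = "gwas"
        hp_means = (
            pheno_table.query("trait == 'SDM' and treatment == 'HP'")
            .groupby("accession")["value"].mean()
        )
        results = association.run_gwas(matrix, hp_means, trait_name="SDM_HP")
        result.results = results
        selected, tier = association.select_significant(
            results, primary=config.primary, fallback=config.fallback,
        )
        result.selected, result.tier = selected, tier
        _write(paths, outdir, "gwas", "gwas_results.tsv",
               lambda p: _io.write_tsv(association.results_to_frame(results, tier), p))
        qq, _ = association.manhattan_qq_tables(results)
        _write(paths, outdir, "qq", "qq_table.tsv", lambda p: _io.write_tsv(qq, p))

        causal = loci[0]
        diag = simdata.diagnostic_kmers(ref, causal, k=config.k)
        by_canon = {kmer_mod.canonicalize(r.kmer): r for r in results}
        diag_scores = np.array([
            by_canon[d].neg_log10_p for d in sorted(diag) if d in by_canon
        ])
        result.diagnostic_neglog10p = diag_scores

        stage = "fragments"
        frags = frag_mod.extend_fragments([r.kmer for r in selected]) if selected else []
        frags = frag_mod.map_fragments(frags, ref)
        result.fragment_list = frags
        _write(paths, outdir, "fragments", "fragments.tsv",
               lambda p: _io.write_tsv(frag_mod.fragments_to_frame(frags, tier), p))
        candidates = frag_mod.annotate_fragments(
            frags, ref.contig_lengths(), ref.genes, half_width=config.half_width,
        )
        result.candidates = candidates
        _write(paths, outdir, "candidates", "candidates.tsv",
               lambda p: _io.write_tsv(candidates, p))
        result.planted_gene_recovered = bool(
            (candidates["gene_id"] == planted_gene).any()
        )

        stage = "pheno_indices"
        result.indices = pheno_mod.efficiency_indices(pheno_table)
        _write(paths, outdir, "indices", "indices.tsv",
               lambda p: _io.write_tsv(result.indices, p))
        groups = pheno_mod.delta_rdm_groups(
            pheno_table, trait="RDM", n_extreme=config.n_extreme, n_pick=config.n_pick,
        )
        result.groups = groups
        _write(paths, outdir, "groups", "delta_rdm_groups.tsv",
               lambda p: _io.write_tsv(groups, p))

        stage = "rsa"
        result.rsa_table = _rsa_stage(config, groups, seeds[7], outdir, paths)

        stage = "manifest"
        _finalise(result, config)
        return result
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 — re-raise with the stage named
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _root_segments(rng: np.random.Generator, canvas: tuple[int, int], low_p: bool):
    """A simple taproot-plus-laterals system; LP systems are a little
    shorter but laterally wider, mimicking topsoil foraging."""
    H, W = canvas
    depth = rng.uniform(0.72, 0.92) * (H - 40) * (0.88 if low_p else 1.0)
    x0 = W / 2 + rng.uniform(-20, 20)
    width = rng.uniform(5.0, 7.0)
    segs = [(x0, 20.0, x0 + rng.uniform(-15, 15), 20.0 + depth, width)]
    n_lat = rng.integers(3, 7)
    for _ in range(n_lat):
        y = rng.uniform(40.0, 20.0 + depth * 0.8)
        reach = rng.uniform(0.15, 0.42) * W * (1.25 if low_p else 1.0)
        reach = min(reach, min(x0, W - x0) - 12)
        direction = 1 if rng.random() < 0.5 else -1
        segs.append((
            x0, y, x0 + direction * reach, y + rng.uniform(10, 60),
            max(3.5, width * rng.uniform(0.5, 0.8)),
        ))
    return segs


def _rsa_stage(config, groups, seed, outdir, paths) -> pd.DataFrame:
    subset = groups[groups["group"] != "none"]["accession"].tolist()
    children = np.random.SeedSequence(seed).spawn(len(subset))
    rows = []
    for acc, child in zip(subset, children):
        rng = np.random.default_rng(child)
        for treatment in ("HP", "LP"):
            mask, _truth = simdata.render_root_mask(
                _root_segments(rng, config.rsa_canvas, low_p=treatment == "LP"),
                config.rsa_canvas, dpi=config.dpi,
            )
            traits = rsa_mod.extract_traits(mask, dpi=config.dpi)
            row = {"accession": acc, "treatment": treatment}
            row.update(traits.as_dict())
            rows.append(row)
    table = pd.DataFrame(rows)
    _write(paths, outdir, "rsa_traits", "rsa_traits.tsv",
           lambda p: _io.write_tsv(table, p))
    wide = table.set_index(["accession", "treatment"]).unstack("treatment")
    wide.columns = [f"{t}_{tr}" for t, tr in wide.columns]
    cluster = rsa_mod.zscore_cluster(wide, n_clusters=2)
    labels = cluster.labels.rename_axis("accession").reset_index()
    _write(paths, outdir, "rsa_clusters", "rsa_clusters.tsv",
           lambda p: _io.write_tsv(labels, p))
    newick = rsa_mod.linkage_to_newick(cluster.linkage, list(wide.index))
    _write(paths, outdir, "rsa_tree", "rsa_tree.nwk",
           lambda p: Path(p).write_text(newick + "\n"))
    return table


def _run_external(config: RunConfig, outdir: Path, result: PipelineResult) -> PipelineResult:
    """Phenotype-only mode on user-supplied tables (no simulation)."""
    if not config.phenotype_tsv:
        raise PipelineError(
            "stage 'inputs' failed: simulation disabled and no phenotype_tsv given"
        )
    path = Path(config.phenotype_tsv)
    if not path.exists():
        raise PipelineError(f"stage 'inputs' failed: phenotype file {path} is missing")
    table = _io.read_tsv(path)
    result.indices = pheno_mod.efficiency_indices(table)
    _write(result.paths, outdir, "indices", "indices.tsv",
           lambda p: _io.write_tsv(result.indices, p))
    groups = pheno_mod.delta_rdm_groups(
        table, trait="RDM", n_extreme=config.n_extreme, n_pick=config.n_pick,
    )
    result.groups = groups
    _write(result.paths, outdir, "groups", "delta_rdm_groups.tsv",
           lambda p: _io.write_tsv(groups, p))
    _finalise(result, config)
    return result


def _finalise(result: PipelineResult, config: RunConfig) -> None:
    outputs = {
        name: {
            "path": str(path.relative_to(result.outdir)),
            "sha256": _io.sha256_of(path),
            "bytes": path.stat().st_size,
        }
        for name, path in sorted(result.paths.items())
    }
    result.manifest = {
        "config": config.as_dict(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": outputs,
    }
    manifest_path = result.outdir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2) + "\n")
    result.paths["manifest"] = manifest_path

    lines = ["# Run summary", ""]
    if result.results is not None:
        lines += [
            f"- accessions: {config.n_accessions}; k = {config.k}; "
            f"MAF ≥ {config.maf_min}",
            f"- k-mers tested: {len(result.results)}",
            f"- significance tier: {result.tier} "
            f"({len(result.selected or [])} selected k-mers)",
            f"- fragments: {len(result.fragment_list or [])}",
            f"- planted gene {result.planted_gene}: "
            f"{'recovered' if result.planted_gene_recovered else 'not recovered'}",
        ]
        if result.diagnostic_neglog10p is not None and len(result.diagnostic_neglog10p):
            lines.append(
                "- median −log10 p of diagnostic k-mers: "
                f"{np.median(result.diagnostic_neglog10p):.2f}"
            )
    summary_path = result.outdir / "summary.md"
    summary_path.write_text("\n".join(lines) + "\n")
    result.paths["summary"] = summary_path
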