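"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_sfs` — Poisson-sampled observed spectra around the
  engine's expected spectrum (for fitting and recovery tests);
* :func:`simulate_vcf` — coalescent genotypes (msprime) for two diploid
  populations plus an outgroup carrying the ancestral allele, under any
  catalog demography, written as a standard VCF with depth, allele-depth
  and quality fields, injected missingness, and physical positions on
  multiple scaffolds;
* :func:`fixture_vcf` — a small hand-designed VCF in which each record
  violates exactly one site-filter rule (or none), with a manifest of
  the expected per-rule outcomes.

The coalescent backend is test scaffolding for the pipeline, not the
inference method: spectra for likelihoods always come from the ODE
engine.  Island models are simulated as two fixed locus classes
(ordinary and island, the island class migrating at rate ``b * m`` in
every epoch), with the island fraction taken from the most recent epoch.
The outgroup split is placed far enough back that ingroup polymorphism
is never shared with the outgroup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import msprime
import numpy as np

from .demography import DemographicModel, bind_parameters
from .engine import DEFAULT_CONFIG, EngineConfig, expected_sfs
from .sfs import JointSFS


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic VCF dataset.

    Defaults emulate the study design the pipeline targets: 27 + 32
    diploid colonies from two depth ecotypes, transcriptome-wide SNPs on
    many short scaffolds, moderate depth with some dropout.
    """

    model_id: str = "e2msa"
    values: tuple = ()
    n1_diploid: int = 27
    n2_diploid: int = 32
    N_ref: float = 10000.0
    mu: float = 1.02e-9
    num_scaffolds: int = 200
    scaffold_length: int = 2000
    missing_rate: float = 0.05
    depth_mean: float = 20.0
    depth_shape: float = 4.0
    qual_mean: float = 500.0
    outgroup_split: float = 8.0       # units of 2 N_ref generations past the root
    island_fraction: float | None = None  # default: newest epoch's P
    polarization_error: float = 0.0
    seed: int = 0
    pop_labels: tuple[str, str] = ("Deep", "Shallow")


def simulate_sfs(model: DemographicModel, values, n1: int, n2: int,
                 theta: float, seed: int | None = None,
                 config: EngineConfig = DEFAULT_CONFIG) -> JointSFS:
    """Poisson-sampled observed spectrum around ``theta * expected``."""
    exp = expected_sfs(model, values, n1, n2, config)
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(exp.counts)
    m = exp.mask
    counts[m] = rng.poisson(theta * exp.counts[m])
    return JointSFS(counts, polarized=True, pop_labels=exp.pop_labels)


def to_msprime_demography(model: DemographicModel, values, N_ref: float,
                          outgroup_split: float | None = None,
                          island_branch: bool = False) -> msprime.Demography:
    """Translate a bound model into an msprime Demography.

    Epoch durations (2 N_ref generations) stack backwards from the
    present; migration uses the diffusion convention validated against
    the engine (forward fraction of pop 1 replaced from pop 2 equals the
    backward lineage rate p1 -> p2).  With ``island_branch`` both
    migration rates are scaled by the model's island factor ``b``.
    """
    anc, epochs = bind_parameters(model, values)
    scale = epochs[0].b if island_branch else 1.0
    newest = epochs[-1]
    dem = msprime.Demography()
    dem.add_population(name="p1", initial_size=newest.nu1 * N_ref)
    dem.add_population(name="p2", initial_size=newest.nu2 * N_ref)
    dem.add_population(name="anc", initial_size=N_ref)
    dem.set_migration_rate("p1", "p2", scale * newest.m12 / (2 * N_ref))
    dem.set_migration_rate("p2", "p1", scale * newest.m21 / (2 * N_ref))
    t = 0.0
    for older, newer in zip(epochs[-2::-1], epochs[::-1]):
        t += newer.T * 2 * N_ref
        dem.add_population_parameters_change(
            time=t, population="p1", initial_size=older.nu1 * N_ref)
        dem.add_population_parameters_change(
            time=t, population="p2", initial_size=older.nu2 * N_ref)
        dem.add_migration_rate_change(
            time=t, source="p1", dest="p2", rate=scale * older.m12 / (2 * N_ref))
        dem.add_migration_rate_change(
            time=t, source="p2", dest="p1", rate=scale * older.m21 / (2 * N_ref))
    t_split = t + epochs[0].T * 2 * N_ref
    dem.add_population_split(time=t_split, derived=["p1", "p2"], ancestral="anc")
    t_root = t_split
    if anc is not None:
        dem.add_population_parameters_change(
            time=t_split, population="anc", initial_size=anc.nu1 * N_ref)
        t_root += anc.T * 2 * N_ref
        dem.add_population_parameters_change(
            time=t_root, population="anc", initial_size=N_ref)
    if outgroup_split is not None:
        dem.add_population(name="out", initial_size=N_ref)
        dem.add_population(name="root", initial_size=N_ref)
        dem.add_population_split(time=t_root + outgroup_split * 2 * N_ref,
                                 derived=["anc", "out"], ancestral="root")
    dem.sort_events()
    return dem


def _qual_and_depth(rng, cfg, n_samples):
    dp = rng.negative_binomial(
        cfg.depth_shape, cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean),
        size=n_samples)
    qual = float(rng.gamma(3.0, cfg.qual_mean / 3.0))
    return dp, round(qual, 1)


def simulate_vcf(cfg: SimulationConfig, vcf_path, popmap_path=None,
                 truth_path=None, model: DemographicModel | None = None) -> dict:
    """Simulate a two-population VCF plus outgroup ancestral alleles.

    Writes a standard VCF 4.2 with GT:DP:AD fields and an ``AA`` INFO tag
    from the outgroup individual's (hom) genotype; REF/ALT are randomly
    swapped relative to ancestral/derived so polarization is exercised in
    both directions.  Returns the truth record (also written to
    ``truth_path`` if given).
    """
    from .demography import get_model
    model = model if model is not None else get_model(cfg.model_id)
    rng = np.random.default_rng(cfg.seed)
    _, epochs = bind_parameters(model, cfg.values)
    p_island = cfg.island_fraction
    if p_island is None:
        p_island = epochs[-1].P
    n_island = int(round(p_island * cfg.num_scaffolds))
    dems = {False: to_msprime_demography(model, cfg.values, cfg.N_ref,
                                         cfg.outgroup_split, False)}
    if n_island:
        dems[True] = to_msprime_demography(model, cfg.values, cfg.N_ref,
                                           cfg.outgroup_split, True)
    samples = [f"{cfg.pop_labels[0]}_{i:03d}" for i in range(cfg.n1_diploid)] + \
              [f"{cfg.pop_labels[1]}_{i:03d}" for i in range(cfg.n2_diploid)]
    n_ing = len(samples)

    import pysam
    header = pysam.VariantHeader()
    header.add_line('##source=sfsflow-simulate')
    for k in range(cfg.num_scaffolds):
        header.contigs.add(f"scaffold_{k:04d}", length=cfg.scaffold_length)
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele (outgroup)">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    for s in samples:
        header.add_sample(s)

    n_sites = 0
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for k in range(cfg.num_scaffolds):
            island = k < n_island
            ts = msprime.sim_ancestry(
                samples={"p1": cfg.n1_diploid, "p2": cfg.n2_diploid, "out": 1},
                demography=dems[island], ploidy=2,
                sequence_length=cfg.scaffold_length,
                random_seed=int(rng.integers(1, 2**31 - 1)))
            ts = msprime.sim_mutations(
                ts, rate=cfg.mu, random_seed=int(rng.integers(1, 2**31 - 1)))
            used = set()
            for var in ts.variants():
                alleles = var.alleles
                if len(alleles) != 2:
                    continue  # keep the output biallelic; filters are tested on fixtures
                pos = int(var.site.position) + 1
                if pos in used or pos > cfg.scaffold_length:
                    continue
                used.add(pos)
                g = var.genotypes
                out_gt = g[2 * n_ing:2 * n_ing + 2]
                if out_gt[0] != out_gt[1]:
                    aa = "."
                else:
                    aa = alleles[out_gt[0]]
                    if cfg.polarization_error and rng.random() < cfg.polarization_error:
                        aa = alleles[1 - out_gt[0]]
                swap = bool(rng.random() < 0.5)
                ref, alt = (alleles[1], alleles[0]) if swap else alleles
                dp, qual = _qual_and_depth(rng, cfg, n_ing)
                rec = out.new_record(contig=f"scaffold_{k:04d}", start=pos - 1,
                                     stop=pos, alleles=(ref, alt), qual=qual)
                rec.info["AA"] = aa
                for si, s in enumerate(samples):
                    a0, a1 = int(g[2 * si]), int(g[2 * si + 1])
                    if swap:
                        a0, a1 = 1 - a0, 1 - a1
                    if rng.random() < cfg.missing_rate:
                        rec.samples[s]["GT"] = (None, None)
                        continue
                    d = int(dp[si])
                    if a0 != a1:
                        alt_reads = int(rng.binomial(d, 0.5))
                    else:
                        alt_reads = d if a0 == 1 else 0
                    rec.samples[s]["GT"] = (a0, a1)
                    rec.samples[s]["DP"] = d
                    rec.samples[s]["AD"] = (d - alt_reads, alt_reads)
                out.write(rec)
                n_sites += 1
    if popmap_path is not None:
        with open(popmap_path, "w") as fh:
            for s in samples:
                pop = cfg.pop_labels[0] if s.startswith(cfg.pop_labels[0]) else cfg.pop_labels[1]
                fh.write(f"{s}\t{pop}\n")
    truth = {"config": asdict(cfg), "model_id": model.id,
             "n_island_scaffolds": n_island, "n_sites_written": n_sites}
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
    return truth


# ---------------------------------------------------------------------------
# hand-designed filter fixture


def _gt_field(gt, dp=20, ad=None):
    if gt is None:
        return "./.:.:.,."
    a, b = gt
    if ad is None:
        alt_reads = dp if (a == 1 and b == 1) else (dp // 2 if a != b else 0)
        ad = (dp - alt_reads, alt_reads)
    return f"{a}/{b}:{dp}:{ad[0]},{ad[1]}"


def fixture_vcf(vcf_path, popmap_path=None):
    """Write a small VCF where each record violates exactly one filter rule.

    Two populations of 12 diploids each.  Returns a manifest of the
    expected drop count per rule and retained/polarized/thinned site
    counts under the default :class:`~sfsflow.vcf_filters.FilterConfig`.
    """
    n_per_pop = 12
    samples = [f"A{i:02d}" for i in range(n_per_pop)] + \
              [f"B{i:02d}" for i in range(n_per_pop)]

    def record(chrom, pos, ref, alt, qual, info, gts):
        cols = [chrom, str(pos), ".", ref, alt, str(qual), ".", info,
                "GT:DP:AD"] + gts
        return "\t".join(cols)

    het = (0, 1)
    homr = (0, 0)
    homa = (1, 1)
    # clean genotype block: both pops segregating and comfortably in HWE
    clean = ([_gt_field(homr)] * 6 + [_gt_field(het)] * 4 + [_gt_field(homa)] * 2) * 2

    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "##contig=<ID=chr1,length=100000>",
        "##contig=<ID=chr2,length=100000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        # retained, ancestral = REF
        record("chr1", 100, "A", "G", 900, "AA=A", clean),
        # an indel record (footprint 2000..2001, buffer 30)
        record("chr1", 2000, "AT", "A", 900, ".", [_gt_field(homr)] * 24),
        # SNP 25 bp from the indel footprint -> indel_proximity
        record("chr1", 2026, "C", "T", 900, "AA=C", clean),
        # triallelic -> biallelic_snp
        record("chr1", 3000, "A", "G,T", 900, "AA=A", [_gt_field(homr)] * 24),
        # QUAL below 30 -> min_qual
        record("chr1", 4000, "A", "G", 29, "AA=A", clean),
        # low depth in 4/12 pop-1 genotypes -> masked -> max_missing
        record("chr1", 5000, "A", "G", 900, "AA=A",
               [_gt_field(het, dp=2)] * 4 + [_gt_field(homr)] * 8
               + [_gt_field(homr)] * 12),
        # pooled heterozygote allele balance 10/90 -> allele_balance
        record("chr1", 6000, "A", "G", 900, "AA=A",
               [_gt_field(het, dp=20, ad=(2, 18))] * 5 + [_gt_field(homr)] * 7
               + [_gt_field(homr)] * 12),
        # extreme homozygote excess in pop 1 (p ~ 3e-4) -> hwe
        record("chr1", 7000, "A", "G", 900, "AA=A",
               [_gt_field(homr)] * 6 + [_gt_field(homa)] * 6
               + [_gt_field(homr)] * 12),
        # retained, ancestral = ALT (polarity swap)
        record("chr2", 100, "A", "G", 900, "AA=G", clean),
        # retained but unpolarizable (outgroup third allele)
        record("chr2", 600, "A", "G", 900, "AA=T", clean),
        # retained; 450 bp from previous retained site -> thinned out
        record("chr2", 1050, "A", "G", 900, "AA=A", clean),
    ]
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if popmap_path is not None:
        with open(popmap_path, "w") as fh:
            for s in samples:
                fh.write(f"{s}\t{'pop1' if s.startswith('A') else 'pop2'}\n")
    manifest = {
        "input_snp_records": 10,
        "indel_records": 1,
        "dropped": {"indel_proximity": 1, "biallelic_snp": 1, "min_qual": 1,
                    "max_missing": 1, "allele_balance": 1, "hwe": 1},
        "retained": 4,
        "polarized": 3,
        "unpolarized_third_allele": 1,
        "after_thinning": 2,
    }
    return manifest
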