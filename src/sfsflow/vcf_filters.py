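"""Deterministic VCF filtering to an analysis-ready polarized site table.

The chain reproduces a conservative RNAseq/RAD SNP-filtering recipe for
demographic inference, applied in a fixed, logged order:

1. drop sites within a buffer of any indel's reference footprint;
2. keep biallelic SNPs only;
3. set genotypes with per-genotype depth below ``min_dp`` to missing;
4. drop sites with QUAL below ``min_q``;
5. drop sites where either population has fewer than 90% of genotypes
   called (the vcftools ``--max-missing`` convention: the threshold is
   the required *present* fraction);
6. drop sites failing pooled allele balance: among heterozygous
   genotypes, the reads supporting each allele must each make up at
   least ``ab_min`` of the heterozygote read total (vcflib convention);
7. drop sites out of Hardy-Weinberg equilibrium in either population,
   by a from-scratch exact test (sum of heterozygote configurations no
   more probable than the observed one, no mid-p).

Under-sequenced individuals (more than half their genotypes missing)
are removed before the site filters.  Polarization against a supplied
outgroup allele turns retained sites into derived/ancestral counts, and
position thinning keeps one SNP per window per scaffold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import pysam

from .sfs import SITE_COLUMNS


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    min_dp: int = 5
    min_q: float = 30.0
    max_missing_frac_per_pop: float = 0.1
    ab_min: float = 0.20
    hwe_p_threshold: float = 0.001
    thin_bp: int = 1000
    indel_buffer_bp: int = 30
    indiv_missing_max: float = 0.5
    biallelic_only: bool = True
    strict: bool = True

    def __post_init__(self):
        if self.thin_bp < 1:
            raise FilterError("thin_bp must be >= 1")
        for name in ("max_missing_frac_per_pop", "ab_min", "indiv_missing_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise FilterError(f"{name} must lie in [0, 1]")
        if not 0 <= self.hwe_p_threshold <= 1:
            raise FilterError("hwe_p_threshold must lie in [0, 1]")


def read_popmap(path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> ordered mapping.

    Population 1 is the first label encountered; the orientation of every
    downstream spectrum follows this order.
    """
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            popmap[sample] = pop
    if len(set(popmap.values())) != 2:
        raise FilterError("population map must define exactly two populations")
    return popmap


def pop_labels(popmap: dict[str, str]) -> tuple[str, str]:
    seen: list[str] = []
    for p in popmap.values():
        if p not in seen:
            seen.append(p)
    return tuple(seen)  # type: ignore[return-value]


def drop_undersequenced_individuals(vcf_path, max_missing: float = 0.5,
                                    out_path=None):
    """Remove samples called at fewer than ``1 - max_missing`` of sites.

    Returns ``(kept_samples, log)`` where log maps removed sample ->
    fraction of sites at which it was called.  If ``out_path`` is given,
    a sample-subset VCF is written.
    """
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        called = dict.fromkeys(samples, 0)
        total = 0
        for rec in vcf:
            total += 1
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is not None and None not in gt:
                    called[s] += 1
    if total == 0:
        raise FilterError("VCF contains no records")
    frac = {s: called[s] / total for s in samples}
    kept = [s for s in samples if frac[s] >= 1.0 - max_missing]
    removed = {s: frac[s] for s in samples if s not in kept}
    if not kept:
        raise FilterError("all samples removed as under-sequenced")
    if out_path is not None:
        with pysam.VariantFile(str(vcf_path)) as vcf:
            vcf.subset_samples(kept)
            with pysam.VariantFile(str(out_path), "w", header=vcf.header) as out:
                for rec in vcf:
                    out.write(rec)
    return kept, removed


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote configurations no more probable than the observed
    one (Wigginton-style, no mid-p correction).
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or not float(v).is_integer():
            raise FilterError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise FilterError("no genotypes")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0

    def logprob(h):
        """log P(het = h | n, rare) up to the shared normalizer."""
        n_hom_rare = (rare - h) // 2
        n_hom_com = n - h - n_hom_rare
        return (h * math.log(2.0) - math.lgamma(n_hom_rare + 1)
                - math.lgamma(h + 1) - math.lgamma(n_hom_com + 1))

    hs = [h for h in range(rare % 2, rare + 1, 2) if (n - h - (rare - h) // 2) >= 0]
    logs = np.array([logprob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n_Aa)]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


RULES = ["indel_proximity", "biallelic_snp", "min_qual", "max_missing",
         "allele_balance", "hwe"]


def _indel_windows(vcf_path, buffer_bp):
    """Per-chromosome sorted arrays of (start, end) indel footprints +- buffer."""
    wins: dict[str, list[tuple[int, int]]] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if any(len(a) != len(rec.ref) for a in alts if a is not None):
                start = rec.pos - buffer_bp
                end = rec.pos + len(rec.ref) - 1 + buffer_bp
                wins.setdefault(rec.chrom, []).append((start, end))
    merged = {}
    for chrom, ivs in wins.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (np.array([s for s, _ in out]), np.array([e for _, e in out]))
    return merged


def _near_indel(windows, chrom, pos):
    if chrom not in windows:
        return False
    starts, ends = windows[chrom]
    i = np.searchsorted(starts, pos, side="right") - 1
    return i >= 0 and pos <= ends[i]


def site_filters(vcf_path, populations: dict[str, str], config: FilterConfig,
                 out_vcf=None):
    """Apply the site-filter chain; returns ``(records, report)``.

    ``records`` is a list of dicts for retained sites with per-population
    REF/ALT allele counts (post depth-masking) and any ancestral-allele
    INFO tag; ``report`` logs per-rule drop counts in application order.
    """
    windows = _indel_windows(vcf_path, config.indel_buffer_bp)
    pops = pop_labels(populations)
    drops = dict.fromkeys(RULES, 0)
    records = []
    n_input = n_indel_records = 0
    warned: set[str] = set()

    def lenient(msg):
        if config.strict:
            raise FilterError(msg)
        if msg not in warned:
            warned.add(msg)
            warnings.warn(msg + " (rule skipped)")

    vcf = pysam.VariantFile(str(vcf_path))
    samples = [s for s in vcf.header.samples if s in populations]
    if not samples:
        raise FilterError("population map covers no VCF sample")
    out = None
    if out_vcf is not None:
        out = pysam.VariantFile(str(out_vcf), "w", header=vcf.header)

    for rec in vcf:
        alts = [a for a in (rec.alts or ()) if a is not None]
        if any(len(a) != len(rec.ref) for a in alts):
            n_indel_records += 1
            continue
        n_input += 1
        # (1) indel proximity
        if _near_indel(windows, rec.chrom, rec.pos):
            drops["indel_proximity"] += 1
            continue
        # (2) biallelic SNP
        if config.biallelic_only and (len(alts) != 1 or len(rec.ref) != 1
                                      or len(alts[0]) != 1):
            drops["biallelic_snp"] += 1
            continue
        # (3) depth masking
        gts = {}
        for s in samples:
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or None in gt:
                gts[s] = None
                continue
            dp = call.get("DP")
            if dp is None:
                lenient(f"site {rec.chrom}:{rec.pos} lacks DP; depth rule skipped")
            elif dp < config.min_dp:
                gts[s] = None
                continue
            gts[s] = gt
        # (4) site quality
        if rec.qual is None or rec.qual < config.min_q:
            drops["min_qual"] += 1
            continue
        # (5) per-population missingness
        called_ok = True
        for pop in pops:
            members = [s for s in samples if populations[s] == pop]
            if not members:
                continue
            frac = sum(gts[s] is not None for s in members) / len(members)
            if frac < 1.0 - config.max_missing_frac_per_pop:
                called_ok = False
                break
        if not called_ok:
            drops["max_missing"] += 1
            continue
        # (6) pooled heterozygote allele balance
        het_reads = np.zeros(2)
        ab_ok = True
        for s in samples:
            gt = gts[s]
            if gt is None or gt[0] == gt[1]:
                continue
            ad = rec.samples[s].get("AD")
            if ad is None or ad[0] is None:
                lenient(f"site {rec.chrom}:{rec.pos} lacks AD; "
                        "allele-balance rule skipped")
                het_reads = None
                break
            het_reads += np.array(ad[:2], dtype=float)
        if het_reads is not None and het_reads.sum() > 0:
            fracs = het_reads / het_reads.sum()
            ab_ok = fracs.min() >= config.ab_min
        if not ab_ok:
            drops["allele_balance"] += 1
            continue
        # (7) Hardy-Weinberg exact test per population
        hwe_ok = True
        for pop in pops:
            members = [s for s in samples if populations[s] == pop]
            counts = [0, 0, 0]  # hom-ref, het, hom-alt
            for s in members:
                gt = gts[s]
                if gt is None:
                    continue
                counts[int(gt[0] != 0) + int(gt[1] != 0)] += 1
            if sum(counts) == 0:
                continue
            if hwe_exact_p(*counts) < config.hwe_p_threshold:
                hwe_ok = False
                break
        if not hwe_ok:
            drops["hwe"] += 1
            continue

        allele_counts = {}
        for idx, pop in enumerate(pops, start=1):
            members = [s for s in samples if populations[s] == pop]
            ref_n = alt_n = 0
            for s in members:
                gt = gts[s]
                if gt is None:
                    continue
                alt_n += sum(1 for a in gt if a != 0)
                ref_n += sum(1 for a in gt if a == 0)
            allele_counts[f"ref{idx}"] = ref_n
            allele_counts[f"alt{idx}"] = alt_n
        aa = rec.info.get("AA") if "AA" in rec.info else None
        records.append({"scaffold": rec.chrom, "pos": rec.pos,
                        "ref": rec.ref, "alt": alts[0] if alts else None,
                        "aa": aa, **allele_counts})
        if out is not None:
            for s in samples:
                if gts[s] is None:
                    rec.samples[s]["GT"] = (None, None)
            out.write(rec)
    vcf.close()
    if out is not None:
        out.close()
    report = {"input_snp_records": n_input,
              "indel_records": n_indel_records,
              "rule_order": RULES,
              "dropped": drops,
              "retained": len(records),
              "config": asdict(config)}
    assert report["retained"] + sum(drops.values()) == n_input
    return records, report


def read_outgroup_tsv(path) -> dict[tuple[str, int], str]:
    """Per-site outgroup alleles from a TSV of (scaffold, pos, allele)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, allele = line.split()[:3]
            out[(chrom, int(pos))] = allele.upper()
    return out


def polarize(records: list[dict],
             outgroup_alleles: dict[tuple[str, int], str] | None = None):
    """Polarize filtered sites into a derived/ancestral site table.

    The outgroup allele comes from ``outgroup_alleles`` when given, else
    from each record's ancestral-allele INFO tag.  Sites whose outgroup
    allele is missing or matches neither REF nor ALT are dropped and
    counted.  Returns ``(site_table, log)``.
    """
    rows = []
    log = {"unpolarized_missing": 0, "unpolarized_third_allele": 0}
    for r in records:
        aa = None
        if outgroup_alleles is not None:
            aa = outgroup_alleles.get((r["scaffold"], r["pos"]))
        elif r.get("aa"):
            aa = str(r["aa"]).upper()
        if aa is None or aa in ("N", "."):
            log["unpolarized_missing"] += 1
            continue
        if aa == r["ref"]:
            anc, der = r["ref"], r["alt"]
            d1, d2 = r["alt1"], r["alt2"]
        elif aa == r["alt"]:
            anc, der = r["alt"], r["ref"]
            d1, d2 = r["ref1"], r["ref2"]
        else:
            log["unpolarized_third_allele"] += 1
            continue
        rows.append({"scaffold": r["scaffold"], "pos": r["pos"],
                     "anc": anc, "der": der,
                     "d1": d1, "c1": r["ref1"] + r["alt1"],
                     "d2": d2, "c2": r["ref2"] + r["alt2"]})
    table = pd.DataFrame(rows, columns=SITE_COLUMNS)
    log["polarized"] = len(table)
    return table, log


def thin(sites: pd.DataFrame, thin_bp: int) -> pd.DataFrame:
    """Greedy position thinning: within each scaffold keep the first site,
    then the next site at least ``thin_bp`` away, and so on."""
    if len(sites) == 0:
        return sites.copy()
    ordered = sites.sort_values(["scaffold", "pos"], kind="mergesort")
    if not ordered.index.equals(sites.index):
        warnings.warn("site table was not sorted by (scaffold, pos); sorting")
    keep = []
    last: dict[str, int] = {}
    for idx, row in ordered.iterrows():
        sc, pos = row["scaffold"], row["pos"]
        if sc not in last or pos - last[sc] >= thin_bp:
            keep.append(idx)
            last[sc] = pos
    return ordered.loc[keep].reset_index(drop=True)
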