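"""Simulate the study-design dataset: two depth ecotypes plus outgroup.

Generates a coalescent VCF under a three-epoch secondary-contact model
with a genomic-island class (the best-supported model family for the
candelabrum-coral ecotype pair): symmetric gene flow after the split, an
isolation epoch, then renewed asymmetric gene flow with both populations
expanding.  27 + 32 diploids emulate the sampled colony design; scaffold
counts and theta are scaled down so the whole analysis runs on a laptop.

Writes: results/dataset.vcf, dataset.popmap.tsv, dataset.outgroup... and
the generating truth record.
"""

import json
import pathlib
import sys

from sfsflow.demography import get_model
from sfsflow.simulate import SimulationConfig, simulate_vcf

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

#: three epochs: symmetric migration, isolation, asymmetric recontact;
#: island fraction grows toward the present, island migration nearly shut
TRUTH_MODEL = "sc3ielsm1"
TRUTH_VALUES = (
    0.8, 1.0, 1.0, 0.5,        # epoch 1: T, nu1, nu2, symmetric m
    0.15, 0.6, 1.4,            # epoch 2 (isolation): T, nu1, nu2
    0.05, 1.5, 1.8, 1.5, 0.3,  # epoch 3: T, nu1, nu2, m12, m21
    0.01, 0.05, 0.25,          # island fractions per epoch
    0.05,                      # island migration factor b
)


def run(seed: int = 20201120, scaffolds: int = 500) -> dict:
    RESULTS.mkdir(exist_ok=True)
    cfg = SimulationConfig(
        model_id=TRUTH_MODEL, values=TRUTH_VALUES,
        n1_diploid=27, n2_diploid=32,            # Deep, Shallow
        N_ref=10000.0, mu=1.0e-8,                # scaled-up mu keeps loci short
        num_scaffolds=scaffolds, scaffold_length=3000,
        missing_rate=0.03, depth_mean=25.0, seed=seed,
        pop_labels=("Deep", "Shallow"))
    truth = simulate_vcf(cfg, RESULTS / "dataset.vcf",
                         RESULTS / "dataset.popmap.tsv",
                         RESULTS / "dataset.truth.json")
    print(f"wrote {truth['n_sites_written']} candidate SNPs on "
          f"{scaffolds} scaffolds ({truth['n_island_scaffolds']} island-class)")
    return truth


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 20201120
    run(seed)
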