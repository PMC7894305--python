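"""Fit competing demographic model families to the observed joint SFS.

Fits a short, purpose-chosen subset of the 107-model catalog spanning
the competing hypotheses: strict isolation, continuous gene flow (IM),
two- and three-epoch secondary contact, with and without the
genomic-island migration class.  (The full catalog sweep is the same
loop over `catalog_list()`; the subset keeps the worked example fast.)

Writes: results/fits/<model>.json per model.
"""

import json
import pathlib
import sys
import time

from sfsflow.demography import get_model
from sfsflow.engine import EngineConfig
from sfsflow.inference import fit_model
from sfsflow.sfs import read_sfs

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

MODELS = [
    "e1m0",        # strict isolation
    "e1ms",        # isolation with continuous symmetric migration
    "e1ma",        # continuous asymmetric migration
    "e2m0a",       # secondary contact: isolation then asymmetric flow
    "e2m0ai",      # ... with a genomic-island class
    "sc3ielsm1",   # 3-epoch: sym flow, isolation, asym recontact + islands
]

ENGINE = EngineConfig(dt_fac=0.05, order_buffer=3)


def run(seed: int = 1, n_starts: int = 10, maxiter: int = 150,
        models=MODELS) -> dict:
    data = read_sfs(RESULTS / "joint.sfs")
    outdir = RESULTS / "fits"
    outdir.mkdir(exist_ok=True)
    fits = {}
    for mid in models:
        model = get_model(mid)
        t0 = time.time()
        fit = fit_model(data, model, n_starts=n_starts, seed=seed,
                        config=ENGINE, maxiter=maxiter)
        rec = {"model": mid, "params": fit.params_dict(),
               "log_likelihood": fit.log_likelihood,
               "theta_hat": fit.theta_hat, "AIC": fit.aic, "k": model.k,
               "n_starts": n_starts, "seed": seed,
               "at_bounds": list(fit.at_bounds)}
        with open(outdir / f"{mid}.json", "w") as fh:
            json.dump(rec, fh, indent=1)
        fits[mid] = rec
        print(f"{mid:>10}: LL = {fit.log_likelihood:9.2f}  AIC = {fit.aic:9.2f}"
              f"  theta = {fit.theta_hat:8.1f}  [{time.time()-t0:.0f}s]")
    return fits


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    run(seed)
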