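"""Two-population multi-epoch demographic models and the shipped catalog.

A model describes the history of a pair of diverging populations as an
ancestral population (optionally undergoing a size change before the
split) followed by one to three post-split *epochs*, ordered oldest to
newest.  Within an epoch, relative sizes are constant and migration is
absent, symmetric, or asymmetric.  Models may additionally partition loci
into two classes: ordinary loci exchanging migrants at the epoch's rates,
and "genomic island" loci whose migration is scaled down by a factor
``b`` (one factor per model), with a free island fraction ``P`` per epoch.

Times are measured in units of ``2 N_ref`` generations and migration
rates in units of ``2 N_ref m`` (with ``m`` the fraction of a population
replaced by migrants per generation), the conventions of diffusion-based
SFS inference.

The shipped catalog enumerates exactly 107 models: a set of named models
matching published exemplars, plus a systematic combinatorial family over
epoch count, per-epoch migration mode, island class, and ancestral size
change (see :func:`catalog_list`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml


class ModelError(ValueError):
    """Invalid model id, structure, or parameter binding."""


#: default validity bounds per parameter kind (T and migration may be 0;
#: the optimizer substitutes a small positive floor for its log transform)
DEFAULT_BOUNDS = {
    "nu": (1e-3, 100.0),
    "T": (0.0, 10.0),
    "m": (0.0, 30.0),
    "P": (0.0, 1.0),
    "b": (0.0, 1.0),
}

#: typical-scale starting values per parameter kind, used to centre
#: multi-start perturbations (bound midpoints would sit orders of
#: magnitude from plausible demographies given the wide boxes above)
TYPICAL_START = {"nu": 1.0, "T": 0.3, "m": 1.0, "P": 0.1, "b": 0.1}


def param_kind(name: str) -> str:
    return "nu" if name.startswith("nu") else name[0]

MIG_MODES = ("0", "s", "a")


@dataclass(frozen=True)
class Epoch:
    """One epoch of constant demography.

    T: duration (2 N_ref generations); nu1, nu2: sizes relative to N_ref;
    m12: migration into pop 1 from pop 2 (units 2 N_ref m), m21 reverse;
    P: fraction of loci in the island class during this epoch; b: island
    migration scaling factor in [0, 1].
    """

    T: float
    nu1: float
    nu2: float
    m12: float = 0.0
    m21: float = 0.0
    P: float = 0.0
    b: float = 1.0

    def __post_init__(self):
        if self.T < 0:
            raise ModelError("epoch duration T must be >= 0")
        if self.nu1 <= 0 or self.nu2 <= 0:
            raise ModelError("relative sizes must be positive")
        if self.m12 < 0 or self.m21 < 0:
            raise ModelError("migration rates must be >= 0")
        if not (0 <= self.P <= 1):
            raise ModelError("island fraction P must lie in [0, 1]")
        if not (0 <= self.b <= 1):
            raise ModelError("island factor b must lie in [0, 1]")


@dataclass(frozen=True)
class DemographicModel:
    """A catalog member: structural description plus free-parameter map.

    ``mig_modes`` holds one code per post-split epoch, oldest first:
    ``'0'`` no migration, ``'s'`` symmetric, ``'a'`` asymmetric.
    """

    id: str
    mig_modes: tuple[str, ...]
    islands: bool = False
    anc_change: bool = False

    def __post_init__(self):
        if not 1 <= len(self.mig_modes) <= 3:
            raise ModelError("models have 1-3 post-split epochs")
        if any(m not in MIG_MODES for m in self.mig_modes):
            raise ModelError(f"unknown migration mode in {self.mig_modes}")
        if self.islands and all(m == "0" for m in self.mig_modes):
            raise ModelError("island class is meaningless without migration")

    @property
    def n_epochs(self) -> int:
        return len(self.mig_modes)

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.anc_change:
            names += ["nuA", "TA"]
        for e, mode in enumerate(self.mig_modes, start=1):
            names += [f"T{e}", f"nu1_{e}", f"nu2_{e}"]
            if mode == "s":
                names.append(f"m{e}")
            elif mode == "a":
                names += [f"m12_{e}", f"m21_{e}"]
        if self.islands:
            names += [f"P{e}" for e in range(1, self.n_epochs + 1)]
            names.append("b")
        return tuple(names)

    @property
    def k(self) -> int:
        """Number of independent free parameters (for AIC)."""
        return len(self.param_names)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple(DEFAULT_BOUNDS[param_kind(n)] for n in self.param_names)

    @property
    def typical_start(self) -> tuple[float, ...]:
        return tuple(TYPICAL_START[param_kind(n)] for n in self.param_names)

    def to_dict(self) -> dict:
        return {"id": self.id, "mig_modes": list(self.mig_modes),
                "islands": self.islands, "anc_change": self.anc_change,
                "parameters": list(self.param_names)}

    @staticmethod
    def from_dict(d: dict) -> "DemographicModel":
        return DemographicModel(id=d["id"], mig_modes=tuple(d["mig_modes"]),
                                islands=bool(d.get("islands", False)),
                                anc_change=bool(d.get("anc_change", False)))


def bind_parameters(model: DemographicModel, values) -> tuple[Epoch | None, list[Epoch]]:
    """Map a free-parameter vector onto concrete epochs.

    Returns ``(ancestral, epochs)`` where ``ancestral`` is an Epoch
    describing the pre-split size change (nu1 == nu2 == nuA, no
    migration) or None, and ``epochs`` are the post-split epochs oldest
    first with all symmetry/zero constraints applied.
    """
    values = np.asarray(values, dtype=float)
    names = model.param_names
    if values.shape != (len(names),):
        raise ModelError(f"model {model.id!r} expects {len(names)} parameters "
                         f"({names}), got {values.shape}")
    for name, v, (lo, hi) in zip(names, values, model.bounds):
        if not (lo <= v <= hi):
            raise ModelError(f"parameter {name}={v} outside bounds [{lo}, {hi}]")
    p = dict(zip(names, values))
    anc = None
    if model.anc_change:
        anc = Epoch(T=p["TA"], nu1=p["nuA"], nu2=p["nuA"])
    b = p.get("b", 1.0)
    epochs = []
    for e, mode in enumerate(model.mig_modes, start=1):
        if mode == "0":
            m12 = m21 = 0.0
        elif mode == "s":
            m12 = m21 = p[f"m{e}"]
        else:
            m12, m21 = p[f"m12_{e}"], p[f"m21_{e}"]
        epochs.append(Epoch(T=p[f"T{e}"], nu1=p[f"nu1_{e}"], nu2=p[f"nu2_{e}"],
                            m12=m12, m21=m21,
                            P=p.get(f"P{e}", 0.0) if model.islands else 0.0,
                            b=b if model.islands else 1.0))
    return anc, epochs


# ---------------------------------------------------------------------------
# catalog


_GRAMMAR = re.compile(r"^(a?)e([123])m([0sa]{1,3})(i?)$")

GRAMMAR_HELP = (
    "systematic model ids follow '[a]e<K>m<modes>[i]': optional leading 'a' "
    "for an ancestral size change, 'e<K>' for K in 1..3 post-split epochs, "
    "'m' followed by K migration-mode codes oldest->newest ('0' none, "
    "'s' symmetric, 'a' asymmetric), optional trailing 'i' for a genomic-"
    "island locus class (requires migration in at least one epoch); "
    "e.g. 'e3ms0ai'.  Published exemplar names (sc3ielsm1, iMi, IMisc, ...) "
    "are also accepted."
)

#: exemplar models named in the literature, with structures matching their
#: published descriptions (three-epoch secondary contact with a middle
#: isolation epoch for the best E. flexuosa model, etc.)
_NAMED_STRUCTURES: dict[str, tuple[tuple[str, ...], bool, bool]] = {
    # id: (mig_modes oldest->newest, islands, anc_change)
    "sc3ielsm1": (("s", "0", "a"), True, False),
    "sc3imilm1": (("s", "0", "a"), True, False),   # alternative published name
    "sc3imlsm1": (("0", "s", "a"), True, False),
    "iMi": (("a",), True, False),
    "sc2ielsm2": (("a", "s"), True, False),
    "sc12il": (("a", "s"), True, True),
    "sc12imlsm2": (("a", "a"), True, True),
    "IMisc": (("s", "a"), True, False),
    "Sc2il": (("0", "a"), True, False),
    "Sc2ilsm": (("0", "s"), True, False),
    "Sc2i": (("a", "a"), True, False),
}


def render_id(mig_modes: tuple[str, ...], islands: bool, anc_change: bool) -> str:
    return (("a" if anc_change else "") + f"e{len(mig_modes)}m" +
            "".join(mig_modes) + ("i" if islands else ""))


def model_grammar_parse(model_id: str) -> DemographicModel:
    """Decode a model id (named exemplar or systematic grammar) to a model."""
    if model_id in _NAMED_STRUCTURES:
        modes, isl, anc = _NAMED_STRUCTURES[model_id]
        return DemographicModel(id=model_id, mig_modes=modes, islands=isl,
                                anc_change=anc)
    m = _GRAMMAR.match(model_id)
    if not m:
        raise ModelError(f"cannot parse model id {model_id!r}. {GRAMMAR_HELP}")
    anc, k, modes, isl = m.groups()
    if len(modes) != int(k):
        raise ModelError(f"id {model_id!r} declares {k} epochs but "
                         f"{len(modes)} migration codes. {GRAMMAR_HELP}")
    return DemographicModel(id=model_id, mig_modes=tuple(modes),
                            islands=bool(isl), anc_change=bool(anc))


def _iter_mode_patterns(n_epochs: int):
    if n_epochs == 1:
        for a in MIG_MODES:
            yield (a,)
    else:
        for rest in _iter_mode_patterns(n_epochs - 1):
            for a in MIG_MODES:
                yield rest + (a,)


def catalog_list() -> list[DemographicModel]:
    """The shipped catalog of exactly 107 models.

    Composition: 11 named exemplars; all 1-3-epoch combinations of
    per-epoch migration mode with and without islands (islands requiring
    migration somewhere); ancestral-size-change variants for 1-2-epoch
    models (excluding the no-migration single-epoch variant).
    """
    models = [model_grammar_parse(name) for name in _NAMED_STRUCTURES]
    for anc in (False, True):
        max_epochs = 3 if not anc else 2
        for k in range(1, max_epochs + 1):
            for modes in _iter_mode_patterns(k):
                for isl in (False, True):
                    if isl and all(m == "0" for m in modes):
                        continue
                    if anc and k == 1 and modes == ("0",) and not isl:
                        continue
                    models.append(DemographicModel(
                        id=render_id(modes, isl, anc), mig_modes=modes,
                        islands=isl, anc_change=anc))
    return models


def get_model(model_id: str) -> DemographicModel:
    """Look up a model id in the shipped catalog."""
    for m in catalog_list():
        if m.id == model_id:
            return m
    raise ModelError(f"model {model_id!r} not in catalog. {GRAMMAR_HELP}")


def catalog_to_yaml(path, models: list[DemographicModel] | None = None) -> None:
    """Write the catalog (or a custom model list) as a YAML document list."""
    models = catalog_list() if models is None else models
    with open(path, "w") as fh:
        yaml.safe_dump([m.to_dict() for m in models], fh, sort_keys=False)


def catalog_from_yaml(path) -> list[DemographicModel]:
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    return [DemographicModel.from_dict(d) for d in docs]
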