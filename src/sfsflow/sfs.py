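"""Joint site-frequency spectra: construction, projection, folding, summaries.

The central container is :class:`JointSFS`, an unfolded (or folded)
two-population spectrum whose entry ``counts[i, j]`` is the number (or
expected number) of sites carrying ``i`` derived alleles in the first
population sample and ``j`` in the second.  The corner entries ``(0, 0)``
and ``(n1, n2)`` carry no polymorphism information; they are retained in
storage but masked out of every statistic.

Spectra are built from a *site table*: a :class:`pandas.DataFrame` of
polarized biallelic sites with columns ``scaffold, pos, anc, der, d1, c1,
d2, c2`` (derived and called allele counts per population).  Missing
genotypes are absorbed by hypergeometric projection down to a common
target sample size, the same averaging performed by easySFS: a site with
``c`` called alleles of which ``d`` are derived contributes the expected
spectrum of a ``n_target``-allele subsample drawn without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

SITE_COLUMNS = ["scaffold", "pos", "anc", "der", "d1", "c1", "d2", "c2"]


class SFSError(ValueError):
    """Invalid input to an SFS operation."""


def empty_site_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        SITE_COLUMNS, [str, int, str, str, int, int, int, int])})


def validate_site_table(sites: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise SFSError(f"site table lacks columns {missing}")
    if len(sites) == 0:
        return
    for k in ("1", "2"):
        d, c = sites[f"d{k}"], sites[f"c{k}"]
        if (d < 0).any() or (c < 0).any() or (d > c).any():
            raise SFSError(f"site table violates 0 <= d{k} <= c{k}")
    if (sites["anc"] == sites["der"]).any():
        raise SFSError("ancestral allele equals derived allele at some site")


@dataclass
class JointSFS:
    """Two-population site-frequency spectrum.

    Parameters
    ----------
    counts
        ``(n1+1, n2+1)`` array; entry ``(i, j)`` is the (expected) number
        of sites with ``i`` derived alleles in population 1 and ``j`` in
        population 2.
    polarized
        True for an unfolded (derived/ancestral) spectrum.
    L_effective
        Total callable sequence length in bp, used for per-base summaries
        such as nucleotide diversity and for theta scaling; optional.
    pop_labels
        Names of the two populations, in axis order.
    """

    counts: np.ndarray
    polarized: bool = True
    L_effective: float | None = None
    pop_labels: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise SFSError("counts must be a 2-D array")
        if np.any(self.counts < 0):
            raise SFSError("negative SFS entries")

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True on entries that enter statistics."""
        m = np.ones_like(self.counts, dtype=bool)
        m[0, 0] = False
        m[self.n1, self.n2] = False
        return m

    @property
    def total(self) -> float:
        """Total unmasked (segregating-site) mass."""
        return float(self.counts[self.mask].sum())

    def copy(self) -> "JointSFS":
        return replace(self, counts=self.counts.copy())


def project_site(d_obs: int, n_obs: int, n_target: int) -> np.ndarray:
    """Expected derived-allele-count distribution of a hypergeometric subsample.

    Entry ``d`` is the probability that a subsample of ``n_target`` alleles
    drawn without replacement from ``n_obs`` called alleles (``d_obs`` of
    them derived) contains exactly ``d`` derived copies.  Sites with fewer
    called alleles than the target cannot be projected and return the
    all-zero vector (the site is dropped).
    """
    for name, v in (("d_obs", d_obs), ("n_obs", n_obs), ("n_target", n_target)):
        if not float(v).is_integer() or v < 0:
            raise SFSError(f"{name} must be a non-negative integer, got {v!r}")
    d_obs, n_obs, n_target = int(d_obs), int(n_obs), int(n_target)
    if n_target < 1:
        raise SFSError("n_target must be >= 1")
    if d_obs > n_obs:
        raise SFSError("d_obs exceeds n_obs")
    if n_obs < n_target:
        return np.zeros(n_target + 1)
    return hypergeom.pmf(np.arange(n_target + 1), n_obs, d_obs, n_target)


from functools import lru_cache


@lru_cache(maxsize=128)
def projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """(n_to+1, n_from+1) matrix of hypergeometric projection weights (cached, read-only)."""
    P = np.empty((n_to + 1, n_from + 1))
    for d in range(n_from + 1):
        P[:, d] = project_site(d, n_from, n_to)
    P.setflags(write=False)
    return P


def project_sfs(sfs: JointSFS, n1_target: int, n2_target: int) -> JointSFS:
    """Project a joint SFS down to smaller sample sizes (exact expectation)."""
    if n1_target > sfs.n1 or n2_target > sfs.n2:
        raise SFSError("cannot project a spectrum up")
    P1 = projection_matrix(sfs.n1, n1_target)
    P2 = projection_matrix(sfs.n2, n2_target)
    return replace(sfs, counts=P1 @ sfs.counts @ P2.T)


def build_sfs(sites: pd.DataFrame, n1_target: int, n2_target: int,
              L_effective: float | None = None,
              pop_labels: tuple[str, str] = ("pop1", "pop2")) -> JointSFS:
    """Accumulate a joint SFS from a polarized site table.

    Each site contributes the outer product of its per-population
    hypergeometric projection vectors; sites with fewer called alleles
    than a target in either population contribute nothing.
    """
    validate_site_table(sites)
    counts = np.zeros((n1_target + 1, n2_target + 1))
    if len(sites) == 0:
        import warnings
        warnings.warn("empty site table: returning empty SFS")
        return JointSFS(counts, polarized=True, L_effective=L_effective,
                        pop_labels=pop_labels)
    cache: dict[tuple[int, int, int], np.ndarray] = {}

    def pvec(d, c, nt):
        key = (d, c, nt)
        if key not in cache:
            cache[key] = project_site(d, c, nt)
        return cache[key]

    for d1, c1, d2, c2 in zip(sites["d1"].to_numpy(), sites["c1"].to_numpy(),
                              sites["d2"].to_numpy(), sites["c2"].to_numpy()):
        if c1 < n1_target or c2 < n2_target:
            continue
        counts += np.outer(pvec(int(d1), int(c1), n1_target),
                           pvec(int(d2), int(c2), n2_target))
    return JointSFS(counts, polarized=True, L_effective=L_effective,
                    pop_labels=pop_labels)


def fold(sfs: JointSFS) -> JointSFS:
    """Fold an unfolded spectrum onto minor-allele classes.

    ``folded[i, j] = unfolded[i, j] + unfolded[n1-i, n2-j]`` on the
    lexicographically smaller half; self-conjugate cells are not doubled.
    """
    if not sfs.polarized:
        raise SFSError("spectrum is already folded")
    n1, n2 = sfs.n1, sfs.n2
    out = np.zeros_like(sfs.counts)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            ci, cj = n1 - i, n2 - j
            if (i, j) < (ci, cj):
                out[i, j] = sfs.counts[i, j] + sfs.counts[ci, cj]
            elif (i, j) == (ci, cj):
                out[i, j] = sfs.counts[i, j]
    return replace(sfs, counts=out, polarized=False)


def marginal(sfs: JointSFS, which_pop: int) -> np.ndarray:
    """1-D marginal spectrum of one population (1 or 2); mass conserved."""
    if which_pop == 1:
        return sfs.counts.sum(axis=1)
    if which_pop == 2:
        return sfs.counts.sum(axis=0)
    raise SFSError("which_pop must be 1 or 2")


def nucleotide_diversity(sfs_1d: np.ndarray, n: int, L: float) -> float:
    """Per-base nucleotide diversity pi from a 1-D spectrum.

    pi = sum_i 2 i (n - i) / (n (n - 1)) * xi_i / L over i = 1..n-1.
    """
    if L <= 0:
        raise SFSError("L must be positive")
    if n < 2:
        raise SFSError("n must be >= 2")
    xi = np.asarray(sfs_1d, dtype=float)
    i = np.arange(1, n)
    x = xi[1:n] if len(xi) >= n else np.zeros(n - 1)
    w = 2.0 * i * (n - i) / (n * (n - 1))
    return float((w * x).sum() / L)


def write_sfs(sfs: JointSFS, path) -> None:
    """Write a joint SFS in the dadi/moments flat text format."""
    n1, n2 = sfs.n1, sfs.n2
    tag = "unfolded" if sfs.polarized else "folded"
    mask = (~sfs.mask).astype(int)
    with open(path, "w") as fh:
        fh.write(f"{n1 + 1} {n2 + 1} {tag} "
                 f"\"{sfs.pop_labels[0]}\" \"{sfs.pop_labels[1]}\"\n")
        fh.write(" ".join(repr(float(v)) for v in sfs.counts.ravel()) + "\n")
        fh.write(" ".join(str(int(v)) for v in mask.ravel()) + "\n")


def read_sfs(path) -> JointSFS:
    """Read a joint SFS from the dadi/moments flat text format."""
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln and not ln.startswith("#")]
    header = lines[0].split()
    s1, s2 = int(header[0]), int(header[1])
    polarized = header[2] == "unfolded"
    labels = tuple(t.strip('"') for t in header[3:5]) if len(header) >= 5 else ("pop1", "pop2")
    data = np.array(lines[1].split(), dtype=float).reshape(s1, s2)
    return JointSFS(data, polarized=polarized, pop_labels=labels)  # mask is implied
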