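"""96-channel trinucleotide mutation spectra and signature refitting.

Point substitutions are folded to the pyrimidine frame (a G>A in a TGT
context becomes A[C>T]A on the reverse strand), counted into the standard
96 channels, and refit against a signature catalog by non-negative least
squares on frequency vectors, with exposures renormalized to the simplex
and a reconstruction cosine reported. A multinomial maximum-likelihood
mode and a greedy forward-selection option are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"
CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _FLANKS
    for three in _FLANKS
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ContextVector:
    counts: np.ndarray  # length 96

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("context vector must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "ContextVector") -> "ContextVector":
        return ContextVector(self.counts + other.counts)

    def series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS))


def channel_of(ref: str, alt: str, five: str, three: str) -> str:
    """Fold one substitution with flanks into its pyrimidine-frame channel."""
    if ref in "AG":  # reverse-complement to the pyrimidine frame
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return f"{five}[{ref}>{alt}]{three}"


def count_contexts(variants, reference) -> ContextVector:
    """96-channel spectrum of the SPMs in ``variants``.

    ``reference`` maps chromosome name to sequence (dict of str or a
    pyfaidx.Fasta). Indels are excluded; variants at a contig edge
    (missing a flank) are skipped with a warning.
    """
    counts = np.zeros(96)
    for v in variants:
        if v.vtype != "SPM":
            continue
        seq = reference[v.chrom]
        p0 = v.pos0
        n = len(seq)
        if p0 < 1 or p0 + 1 >= n:
            warnings.warn(f"variant at contig edge skipped: {v.chrom}:{v.pos}")
            continue
        tri = seq[p0 - 1:p0 + 2]
        tri = tri if isinstance(tri, str) else str(tri)
        tri = tri.upper()
        if any(b not in "ACGT" for b in tri) or v.alt not in "ACGT":
            continue
        if tri[1] != v.ref.upper():
            raise ValueError(f"reference mismatch at {v.chrom}:{v.pos}: {tri[1]} vs {v.ref}")
        counts[_CHANNEL_INDEX[channel_of(tri[1], v.alt.upper(), tri[0], tri[2])]] += 1
    return ContextVector(counts)


def count_contexts_by(variants, reference, key) -> dict:
    """Spectra per group (e.g. per sample or per stratum label)."""
    groups: dict = {}
    for v in variants:
        groups.setdefault(key(v), []).append(v)
    return {k: count_contexts(vs, reference) for k, vs in sorted(groups.items())}


# ------------------------------------------------------------- catalog


def make_default_catalog(k: int = 5, seed: int = 12345) -> pd.DataFrame:
    """Synthetic 96 x K catalog of well-separated, spiky signatures.

    Each signature concentrates 70% of its mass on its own block of
    channels, so refitting mixtures of them is well conditioned. Columns
    sum to 1.
    """
    rng = np.random.default_rng(seed)
    sigs = np.empty((96, k))
    blocks = np.array_split(np.arange(96), k)
    for j in range(k):
        base = rng.dirichlet(np.full(96, 0.2))
        spike = np.zeros(96)
        spike[blocks[j]] = rng.dirichlet(np.full(len(blocks[j]), 0.5))
        sigs[:, j] = 0.3 * base + 0.7 * spike
    sigs /= sigs.sum(axis=0, keepdims=True)
    return pd.DataFrame(sigs, index=list(CHANNELS),
                        columns=[f"SBS_TOY{j + 1}" for j in range(k)])


def load_catalog(path) -> pd.DataFrame:
    """Load a 96 x K signature catalog TSV (channels in rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNELS):
        df = df.reindex(list(CHANNELS))
        if df.isna().any().any():
            raise ValueError("catalog does not cover the 96 standard channels")
    return df


# --------------------------------------------------------------- refit


@dataclass
class SignatureExposure:
    exposures: pd.Series  # per-signature fractions, sum to 1
    reconstruction_cosine: float

    def __post_init__(self):
        if (self.exposures < -1e-12).any():
            raise ValueError("negative exposure")


def _cosine(a, b) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def refit(vector: ContextVector, catalog: pd.DataFrame,
          method: str = "nnls", signatures=None) -> SignatureExposure:
    """Refit a spectrum against a catalog.

    ``method='nnls'`` solves non-negative least squares on the normalized
    frequency vector; ``method='mle'`` maximizes the multinomial
    log-likelihood over the exposure simplex. ``signatures`` restricts the
    catalog columns used.
    """
    if vector.total == 0:
        raise ValueError("cannot refit an empty spectrum")
    cols = list(catalog.columns) if signatures is None else list(signatures)
    S = catalog[cols].to_numpy(dtype=float)
    if not np.allclose(S.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("catalog columns must each sum to 1")
    v = vector.counts / vector.total
    if method == "nnls":
        x, _ = optimize.nnls(S, v)
    elif method == "mle":
        k = S.shape[1]

        def negll(z):
            w = np.exp(z - z.max())
            w /= w.sum()
            p = S @ w + 1e-12
            return -(vector.counts @ np.log(p))

        best = optimize.minimize(negll, np.zeros(k), method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
        x = np.exp(best.x - best.x.max())
    else:
        raise ValueError(f"unknown method {method!r}")
    if x.sum() == 0:
        x = np.full(len(cols), 1.0 / len(cols))
    exposures = x / x.sum()
    recon = S @ exposures
    return SignatureExposure(
        exposures=pd.Series(exposures, index=cols),
        reconstruction_cosine=_cosine(recon, v),
    )


def refit_forward_selection(vector: ContextVector, catalog: pd.DataFrame,
                            min_gain: float = 0.01, method: str = "nnls") -> SignatureExposure:
    """Greedy subset search: add the signature that most improves the
    reconstruction cosine until the gain drops below ``min_gain``."""
    remaining = list(catalog.columns)
    chosen: list[str] = []
    best_fit = None
    best_cos = -np.inf
    while remaining:
        trial_results = [
            (refit(vector, catalog, method=method, signatures=chosen + [c]), c)
            for c in remaining
        ]
        fit, col = max(trial_results, key=lambda t: t[0].reconstruction_cosine)
        if fit.reconstruction_cosine - best_cos < min_gain and chosen:
            break
        chosen.append(col)
        remaining.remove(col)
        best_fit, best_cos = fit, fit.reconstruction_cosine
    full = pd.Series(0.0, index=catalog.columns)
    full[best_fit.exposures.index] = best_fit.exposures
    return SignatureExposure(exposures=full, reconstruction_cosine=best_cos)
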