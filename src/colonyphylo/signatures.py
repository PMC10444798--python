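"""96-channel mutation spectra and fixed-signature refitting.

Single-base substitutions are classified into 96 channels: six pyrimidine
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) times the 16 flanking
trinucleotide contexts. Mutations recorded on the purine strand are
reverse-complemented into the pyrimidine convention. Given fixed reference
signature probability vectors, per-colony or per-branch proportions are
refit by multinomial maximum likelihood (EM), which is the standard
refitting model behind tools of the sigfit family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "CHANNELS",
    "Spectrum96",
    "SignatureFit",
    "compute_spectrum",
    "fit_signature_proportions",
    "cosine_similarity",
    "decompose_trunk",
    "pooled_profile",
    "synthetic_reference_signatures",
]

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]
CHANNELS: list[str] = [
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def channel_of(context: str, ref: str, alt: str) -> str:
    """Map a trinucleotide context + ref/alt to its pyrimidine-strand channel.

    ``context`` is the 3-mer centred on the mutated base as recorded
    (either strand); the mapping is the identity on contexts already in
    pyrimidine convention.
    """
    context = str(context).upper()
    ref = str(ref).upper()
    alt = str(alt).upper()
    if (
        len(context) != 3
        or any(b not in _COMP for b in context)
        or ref not in _COMP
        or alt not in _COMP
        or ref == alt
        or context[1] != ref
    ):
        raise DataError(f"malformed trinucleotide record: context={context} {ref}>{alt}")
    if ref in ("A", "G"):
        context = _revcomp(context)
        ref = _COMP[ref]
        alt = _COMP[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class Spectrum96:
    """Nonnegative counts over the 96 trinucleotide channels."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalised(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalise an empty spectrum")
        return self.counts / self.total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CHANNELS, name="count")


@dataclass
class SignatureFit:
    """Mixture proportions of fixed reference signatures for one spectrum."""

    proportions: pd.Series
    cosine: float
    attributed: pd.Series  # mutation counts credited to each signature
    log_likelihood: float


def compute_spectrum(mutations: pd.DataFrame, dedup: bool = False, rng=None) -> Spectrum96:
    """Aggregate mutation records into a 96-channel spectrum.

    ``mutations`` needs columns context/ref/alt; with ``dedup`` enabled,
    records sharing a site id (mutations carried by several colonies)
    contribute once, attributed to one record chosen uniformly at random.
    """
    required = {"context", "ref", "alt"}
    missing = required - set(mutations.columns)
    if missing:
        raise DataError(f"mutation table lacks columns: {sorted(missing)}")
    df = mutations
    if dedup:
        rng = np.random.default_rng(rng)
        if "site_id" in df.columns:
            key = df["site_id"]
        else:
            key = df.index
        order = rng.permutation(len(df))
        df = df.iloc[order]
        df = df[~pd.Index(key).take(order).duplicated()]
    counts = np.zeros(96)
    bad = []
    for sid, ctx, ref, alt in zip(df.index, df["context"], df["ref"], df["alt"]):
        try:
            counts[_CHANNEL_INDEX[channel_of(ctx, ref, alt)]] += 1
        except DataError:
            bad.append(sid)
    if bad:
        raise DataError(f"malformed trinucleotide context for records: {bad[:10]}")
    return Spectrum96(counts)


def cosine_similarity(a, b) -> float:
    """Cosine of two nonnegative 96-channel vectors or spectra."""
    va = a.counts if isinstance(a, Spectrum96) else np.asarray(a, dtype=float)
    vb = b.counts if isinstance(b, Spectrum96) else np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


def fit_signature_proportions(
    spectrum: Spectrum96, refs: pd.DataFrame, tol: float = 1e-8, max_iter: int = 10000
) -> SignatureFit:
    """Multinomial maximum-likelihood refit of fixed signatures.

    ``refs`` is a 96 x K DataFrame of probability vectors (columns are
    signatures). EM from equal initial proportions; iterates until the
    log-likelihood gain falls below ``tol``.
    """
    x = spectrum.counts
    n = x.sum()
    if n == 0:
        raise ValueError("zero-total spectrum")
    R = refs.to_numpy(dtype=float)
    if R.shape[0] != 96 or (R < 0).any():
        raise ValueError("reference matrix must be 96 x K, nonnegative")
    R = R / R.sum(axis=0)
    K = R.shape[1]
    pi = np.full(K, 1.0 / K)
    eps = 1e-300
    last = -np.inf
    for _ in range(max_iter):
        mix = R @ pi  # per-channel probability
        ll = float(np.sum(x * np.log(mix + eps)))
        # responsibilities: channel c, signature k
        z = (R * pi[None, :]) / (mix[:, None] + eps)
        pi = (x[:, None] * z).sum(axis=0) / n
        if ll - last < tol and ll >= last:
            break
        last = ll
    mix = R @ pi
    recon = mix * n
    cos = cosine_similarity(x, recon)
    props = pd.Series(pi, index=refs.columns, name="proportion")
    return SignatureFit(
        proportions=props,
        cosine=cos,
        attributed=props * n,
        log_likelihood=float(np.sum(x * np.log(mix + eps))),
    )


def pooled_profile(spectra) -> np.ndarray:
    """Pooled (summed) spectrum of several colonies/branches, normalised."""
    total = np.zeros(96)
    for s in spectra:
        total += s.counts if isinstance(s, Spectrum96) else np.asarray(s, dtype=float)
    if total.sum() == 0:
        raise ValueError("pooled profile is empty")
    return total / total.sum()


def decompose_trunk(trunk: Spectrum96, composite_profile, transformation_profile):
    """Split a shared-trunk spectrum into steady-state and transformation parts.

    ``composite_profile`` is the pooled, normalised spectrum of comparator
    individuals (the mutational profile of untransformed haematopoiesis at
    a matched age); ``transformation_profile`` comes from the transformed
    clade's private end branches. Returns (proportion_composite,
    proportion_transformation, reconstruction cosine).
    """
    comp = np.asarray(composite_profile, dtype=float)
    trans = np.asarray(transformation_profile, dtype=float)
    refs = pd.DataFrame({"composite": comp, "transformation": trans})
    fit = fit_signature_proportions(trunk, refs)
    return (
        float(fit.proportions["composite"]),
        float(fit.proportions["transformation"]),
        fit.cosine,
    )


def synthetic_reference_signatures() -> pd.DataFrame:
    """Synthetic stand-in reference signatures (96 x 2 DataFrame).

    These are *not* the COSMIC vectors: they are simplified, well-separated
    probability profiles used by the simulator and tests. ``SBS1like``
    concentrates on C>T at NpCpG (the clock-like deamination channels);
    ``SBSbloodlike`` is a broad profile over T>C and C>A channels with no
    mass on the NpCpG C>T channels, emulating the endogenous HSC signature.
    """
    sbs1 = np.zeros(96)
    cpg = [f"{five}[C>T]G" for five in BASES]
    for c in cpg:
        sbs1[_CHANNEL_INDEX[c]] = 0.20
    rest = [i for i, c in enumerate(CHANNELS) if c not in cpg]
    sbs1[rest] = 0.20 / len(rest)

    blood = np.zeros(96)
    for i, c in enumerate(CHANNELS):
        if "[T>C]" in c:
            blood[i] = 0.035
        elif "[C>A]" in c:
            blood[i] = 0.020
        elif "[T>A]" in c or "[T>G]" in c:
            blood[i] = 0.004
    blood /= blood.sum()
    sbs1 /= sbs1.sum()
    return pd.DataFrame({"SBS1like": sbs1, "SBSbloodlike": blood}, index=CHANNELS)
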