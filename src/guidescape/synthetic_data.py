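"""Generative model of search-time-limited gRNA activity.

The model treats the genome ("species") a Cas9/gRNA complex operates in as a
pool of inhibitory non-target sites whose composition sets, for every
PAM-proximal k-mer, a *ceiling*: the maximal activity a guide ending in that
k-mer can reach in that context.  Measured activity is the ceiling times two
orthogonal attenuating factors —

* a species-independent multiplicative preference for the genomic nucleotide
  immediately 3' of the NGG PAM (the NGGH preference, G lowest), an intrinsic
  property of the nuclease rather than of the genome, and
* a per-guide attenuation A in (0, 1]: with probability ``p_full`` the guide
  realizes its full ceiling (A = 1), otherwise A ~ Uniform(0, 1) stands in
  for everything that only ever *lowers* activity below the ceiling
  (secondary structure, target accessibility, repair differences, ...)

— plus Gaussian measurement noise.  Because attenuation is multiplicative and
one-sided, a predictor of the ceiling over-predicts but almost never
under-predicts, reproducing the skewed-residual / upper-bound geometry the
analysis modules look for.

Ceilings are drawn i.i.d. logit-normal (logit-scale sd 1) from a
species-specific seed and rescaled so the best k-mer has ceiling 1; the PAM
4th-nt factors are drawn from a separate *intrinsic* seed so that distinct
species share them exactly, mirroring a nuclease-intrinsic effect.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset_io import RAW, Dataset
from .errors import ParameterError

BASES = "ACGT"

#: Span of the PAM 4th-nt multiplicative factors.  The NGGH preference is a
#: weak effect, so factors sit in a narrow band just below 1.
PAM4_FACTOR_LOW = 0.85

DESIGN_FILTERS = ("none", "no_T_proximal4", "fixed_pam4")
READOUTS = ("continuous", "binary")


def all_kmers(k: int) -> list[str]:
    """All 4**k DNA k-mers in lexicographic (A<C<G<T) order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def draw_ceilings(rng: np.random.Generator, size: int, logit_sd: float = 1.0) -> np.ndarray:
    """Raw (pre-rescaling) ceiling draws: expit of Normal(0, logit_sd)."""
    return expit(rng.normal(0.0, logit_sd, size=size))


@dataclass(frozen=True)
class ContextEffectMap:
    """A synthetic species: PAM-proximal k-mer ceilings plus PAM 4th-nt factors."""

    species_id: str
    k: int
    ceiling: Mapping[str, float]
    pam4_factor: Mapping[str, float]

    def ceiling_array(self) -> np.ndarray:
        """Ceilings as a vector in lexicographic k-mer order."""
        return np.array([self.ceiling[m] for m in all_kmers(self.k)], dtype=float)

    def pam4_array(self) -> np.ndarray:
        return np.array([self.pam4_factor[b] for b in BASES], dtype=float)

    def to_manifest(self) -> dict:
        """JSON-serializable truth record (the parameter-recovery target)."""
        return {
            "species_id": self.species_id,
            "k": self.k,
            "model": "synthetic search-time ceiling (logit-normal stand-in)",
            "ceiling": dict(self.ceiling),
            "pam4_factor": dict(self.pam4_factor),
        }


def sample_context(species_seed: int, intrinsic_seed: int, k: int = 5) -> ContextEffectMap:
    """Draw a species context: ceilings from ``species_seed``, PAM factors from
    ``intrinsic_seed`` only.

    Two maps built with different species seeds but the same intrinsic seed
    share their PAM 4th-nt factors exactly and differ in every ceiling.
    The G factor is forced lowest (NGGH preference).  Deterministic.
    """
    if not 1 <= k <= 8:
        raise ParameterError(f"k must be in 1..8, got {k}")
    rng = np.random.default_rng(species_seed)
    c = draw_ceilings(rng, 4**k)
    c /= c.max()

    rng_i = np.random.default_rng(intrinsic_seed)
    f = rng_i.uniform(PAM4_FACTOR_LOW, 1.0, size=4)
    g = BASES.index("G")
    j = int(np.argmin(f))
    f[[g, j]] = f[[j, g]]

    return ContextEffectMap(
        species_id=f"sp{species_seed}",
        k=k,
        ceiling=dict(zip(all_kmers(k), c.tolist())),
        pam4_factor=dict(zip(BASES, f.tolist())),
    )


def shrink_context(m: ContextEffectMap, lam: float) -> ContextEffectMap:
    """Shrink ceilings toward their mean by ``lam`` and rescale to max 1.

    Models interventions that reduce the impact of genomic context on
    activity — higher Cas9/gRNA expression or stricter PAM recognition, both
    of which shorten search times and flatten k-mer-specific differences.
    ``lam=0`` is the identity; ``lam=1`` erases all context structure.
    """
    if not 0.0 <= lam <= 1.0:
        raise ParameterError(f"lam must be in [0, 1], got {lam}")
    c = m.ceiling_array()
    c = (1.0 - lam) * c + lam * c.mean()
    c /= c.max()
    return ContextEffectMap(
        species_id=f"{m.species_id}_shrunk{lam:g}",
        k=m.k,
        ceiling=dict(zip(all_kmers(m.k), c.tolist())),
        pam4_factor=dict(m.pam4_factor),
    )


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of one simulated library.

    ``p_full`` is the probability a guide realizes its full ceiling; the
    default 0.85 makes attenuation the exception rather than the rule, which
    is what gives real activity distributions their ceiling-hugging shape.
    ``noise_sd`` is measurement noise on the [0, 1] activity scale.
    """

    n_guides: int
    seed: int
    noise_sd: float = 0.02
    p_full: float = 0.85
    readout: str = "continuous"
    binary_threshold: float | None = None
    design_filter: str = "none"

    def __post_init__(self) -> None:
        if self.n_guides < 1:
            raise ParameterError("n_guides must be >= 1")
        if not 0.0 <= self.p_full <= 1.0:
            raise ParameterError("p_full must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.readout not in READOUTS:
            raise ParameterError(f"readout must be one of {READOUTS}")
        if self.design_filter not in DESIGN_FILTERS:
            raise ParameterError(f"design_filter must be one of {DESIGN_FILTERS}")


def simulate_dataset(
    m: ContextEffectMap, params: SimulationParams, dataset_id: str | None = None
) -> Dataset:
    """Simulate one gRNA library from a species context.

    Spacers are uniform over 20-mers subject to the design filter
    (``no_T_proximal4`` bans T at spacer positions 17-20, emulating libraries
    designed that way; ``fixed_pam4`` holds the PAM 4th nucleotide at A).
    Activity = ceiling(PAM-proximal k-mer) x pam4_factor(4th nt) x A
    + Normal(0, noise_sd), clipped to [0, 1.05].  A binary readout thresholds
    the continuous value.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_guides
    k = m.k

    codes = rng.integers(0, 4, size=(n, 20))
    if params.design_filter == "no_T_proximal4":
        codes[:, 16:20] = rng.integers(0, 3, size=(n, 4))  # A/C/G only
    base_arr = np.array(list(BASES))
    spacers = ["".join(row) for row in base_arr[codes]]

    pam1 = rng.integers(0, 4, size=n)
    if params.design_filter == "fixed_pam4":
        pam4 = np.zeros(n, dtype=int)  # constant A
    else:
        pam4 = rng.integers(0, 4, size=n)
    pam_contexts = [base_arr[a] + "GG" + base_arr[b] for a, b in zip(pam1, pam4)]

    # Lexicographic k-mer index of the PAM-proximal k spacer positions.
    weights = 4 ** np.arange(k - 1, -1, -1)
    kmer_idx = codes[:, 20 - k :] @ weights
    ceiling = m.ceiling_array()[kmer_idx]
    factor = m.pam4_array()[pam4]

    full = rng.random(n) < params.p_full
    atten = np.where(full, 1.0, rng.random(n))
    activity = ceiling * factor * atten
    if params.noise_sd > 0:
        activity = activity + rng.normal(0.0, params.noise_sd, size=n)
    activity = np.clip(activity, 0.0, 1.05)

    if params.readout == "binary":
        thr = 0.5 if params.binary_threshold is None else params.binary_threshold
        activity = (activity > thr).astype(float)
    elif params.binary_threshold is not None:
        warnings.warn("binary_threshold ignored for continuous readout", stacklevel=2)

    dataset_id = dataset_id or f"{m.species_id}_s{params.seed}"
    df = pd.DataFrame(
        {
            "guide_id": [f"{dataset_id}-{i:06d}" for i in range(n)],
            "spacer": spacers,
            "pam_context": pam_contexts,
            "activity": activity,
        }
    )
    meta = {
        "synthetic": True,
        "species_id": m.species_id,
        "model": "ceiling",
        "k": k,
        "n_guides": n,
        "seed": params.seed,
        "noise_sd": params.noise_sd,
        "p_full": params.p_full,
        "readout": params.readout,
        "design_filter": params.design_filter,
    }
    return Dataset(
        dataset_id=dataset_id, df=df, species=m.species_id, meta=meta, scale_state=RAW
    )


def simulate_planted_window_effect(
    n_guides: int,
    seed: int,
    window: tuple[int, int] = (16, 20),
    noise_sd: float = 0.3,
    dataset_id: str | None = None,
) -> Dataset:
    """Library whose activity is an additive function of the dinucleotides
    wholly inside ``window`` (spacer positions, 1-based inclusive), plus
    Gaussian noise.

    This is the planted-effect oracle for positional ablation: unlike the
    ceiling model — whose i.i.d. k-mer map has almost no additive
    dinucleotide structure for a linear model to find at moderate n — every
    bit of this signal is representable by the dinucleotide encoding and
    confined to the window, so masking the window must erase predictivity.
    """
    start, end = window
    if not 1 <= start < end <= 20:
        raise ParameterError(f"window {window} outside spacer positions 1..20")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n_guides, 20))
    base_arr = np.array(list(BASES))
    spacers = ["".join(row) for row in base_arr[codes]]
    pam_contexts = [
        base_arr[a] + "GG" + base_arr[b]
        for a, b in zip(rng.integers(0, 4, n_guides), rng.integers(0, 4, n_guides))
    ]
    weights = rng.normal(size=(end - start, 16))
    y = np.zeros(n_guides)
    for p in range(end - start):  # pairs (start+p, start+p+1)
        dinuc = 4 * codes[:, start - 1 + p] + codes[:, start + p]
        y += weights[p, dinuc]
    y += rng.normal(0.0, noise_sd, size=n_guides)

    dataset_id = dataset_id or f"planted{start}-{end}_s{seed}"
    df = pd.DataFrame(
        {
            "guide_id": [f"{dataset_id}-{i:06d}" for i in range(n_guides)],
            "spacer": spacers,
            "pam_context": pam_contexts,
            "activity": y,
        }
    )
    meta = {
        "synthetic": True,
        "model": "planted_window_effect",
        "window": list(window),
        "seed": seed,
        "noise_sd": noise_sd,
    }
    return Dataset(dataset_id=dataset_id, df=df, meta=meta, scale_state=RAW)
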