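"""Ancestral intron-count and minor-intron-density reconstruction from three-species data.

The model: for species alpha and beta sister to an outgroup gamma, an intron found in any
two of the three species is (assuming negligible parallel gain) ancestral to the
alpha/beta split.  With per-lineage retention probabilities ``P_x`` and independent loss,

    P_hat_beta = N_abg / N_ag              (retention in beta)
    N_abg      = N_omega * P_a * P_b * P_g
    N_omega    = N_ab * N_ag * N_bg / N_abg**2

where ``N_xy`` counts introns of one type shared between a species pair inside the
three-way alignments and ``N_abg`` those shared by all three.  Running the estimator
separately for minor and major introns gives the ancestral minor intron density

    rho = N_omega_minor / (N_omega_minor + N_omega_major) * 100%

which is normalised to a reference species' density in the same aligned genes and
averaged (mean +/- SEM) over species combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, ParameterError

LINEAGES = ("alpha", "beta", "gamma")

# pair of lineages NOT involving the keyed lineage
_COMPLEMENT_PAIR = {"alpha": "n_bg", "beta": "n_ag", "gamma": "n_ab"}


@dataclass(frozen=True)
class TriplePresenceCounts:
    """Pairwise and three-way shared intron counts for one intron type."""

    n_ab: int
    n_ag: int
    n_bg: int
    n_abg: int
    intron_type: str = "minor"

    def __post_init__(self) -> None:
        counts = (self.n_ab, self.n_ag, self.n_bg, self.n_abg)
        if any(c < 0 for c in counts):
            raise ParameterError(f"negative presence counts: {counts}")
        if self.n_abg > min(self.n_ab, self.n_ag, self.n_bg):
            raise ParameterError(
                "three-way count exceeds a pairwise count: "
                f"N_abg={self.n_abg} > min{counts[:3]}"
            )


@dataclass(frozen=True)
class RetentionEstimate:
    lineage: str
    p_hat: float


@dataclass(frozen=True)
class AncestralDensityEstimate:
    rho_hat: float           # percent
    reference_density: float  # percent
    relative: float           # rho_hat / reference_density


def retention_fraction(counts: TriplePresenceCounts, lineage: str) -> RetentionEstimate:
    """Fraction of ancestral introns retained in ``lineage``.

    P_hat = N_abg / N_pair, with the pair count taken over the two *other* lineages.
    """
    if lineage not in LINEAGES:
        raise ParameterError(f"unknown lineage {lineage!r}; expected one of {LINEAGES}")
    denom = getattr(counts, _COMPLEMENT_PAIR[lineage])
    if denom == 0:
        raise EstimationError(f"retention in {lineage} undefined: pair count is zero")
    return RetentionEstimate(lineage, counts.n_abg / denom)


def estimate_ancestral_count(counts: TriplePresenceCounts) -> float:
    """Estimated number of ancestral introns in the aligned regions.

    N_omega_hat = N_ab * N_ag * N_bg / N_abg**2.  Real-valued; round for reporting.
    """
    if counts.n_abg == 0:
        raise EstimationError("ancestral count undefined: three-way count is zero")
    return counts.n_ab * counts.n_ag * counts.n_bg / counts.n_abg**2


def ancestral_density(n_minor: float, n_major: float) -> float:
    """Ancestral minor intron density (%) from the two ancestral count estimates."""
    if n_minor < 0 or n_major < 0:
        raise ParameterError("ancestral counts must be non-negative")
    total = n_minor + n_major
    if total == 0:
        raise EstimationError("density undefined: both ancestral counts are zero")
    return n_minor / total * 100.0


def relative_density(rho_hat: float, reference_density: float) -> float:
    """Ancestral density normalised to the reference species' density (same genes)."""
    if reference_density <= 0:
        raise ParameterError("reference density must be positive")
    return rho_hat / reference_density


def aggregate(ratios) -> tuple[float, float]:
    """Unweighted mean and SEM (sample sd, n-1) over per-combination estimates.

    SEM is 0.0 for a single estimate.
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ParameterError("no estimates to aggregate")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, sem


def reconstruct_node(
    minor_counts: TriplePresenceCounts,
    major_counts: TriplePresenceCounts,
    reference_density: float,
) -> dict:
    """One full reconstruction for a single species combination.

    Ancestral counts are rounded to the nearest integer for reporting and the density
    is computed from the rounded counts, matching how such estimates are conventionally
    printed (the real-valued estimates are also returned).
    """
    n_minor = estimate_ancestral_count(minor_counts)
    n_major = estimate_ancestral_count(major_counts)
    n_minor_r, n_major_r = round(n_minor), round(n_major)
    rho = ancestral_density(n_minor_r, n_major_r)
    return {
        "n_minor": n_minor,
        "n_major": n_major,
        "n_minor_rounded": n_minor_r,
        "n_major_rounded": n_major_r,
        "rho_pct": rho,
        "relative": relative_density(rho, reference_density),
        "reference_density": reference_density,
    }


def counts_from_states(states: pd.DataFrame, intron_type: str) -> TriplePresenceCounts:
    """Derive TriplePresenceCounts from a per-intron three-taxon state table.

    ``states`` needs columns state_alpha/state_beta/state_gamma with values in
    {'minor','major','absent'}.  An intron counts toward a pair if *both* members show
    the requested type (a converted intron is present as major, never as minor).
    """
    a = states["state_alpha"].to_numpy() == intron_type
    b = states["state_beta"].to_numpy() == intron_type
    g = states["state_gamma"].to_numpy() == intron_type
    return TriplePresenceCounts(
        n_ab=int((a & b).sum()),
        n_ag=int((a & g).sum()),
        n_bg=int((b & g).sum()),
        n_abg=int((a & b & g).sum()),
        intron_type=intron_type,
    )


def loss_decomposition(
    states: pd.DataFrame,
    focal: str = "alpha",
    intron_type: str = "minor",
) -> dict:
    """Decompose the fate of ancestral introns of one type in a focal species.

    The ancestral set is the introns present *as the focal type* in both the sister
    species and the outgroup.  Among those, the focal species either retained the
    intron as the same type, converted it (present as the other type) or deleted it
    (absent).  Conversion estimates are conservative: a conversion followed by
    deletion is indistinguishable from a plain deletion.
    """
    if focal not in LINEAGES:
        raise ParameterError(f"unknown focal lineage {focal!r}")
    others = [ln for ln in LINEAGES if ln != focal]
    anc = states[
        (states[f"state_{others[0]}"] == intron_type)
        & (states[f"state_{others[1]}"] == intron_type)
    ]
    n = len(anc)
    if n == 0:
        raise EstimationError("no ancestral introns of the requested type")
    focal_state = anc[f"state_{focal}"]
    other_type = "major" if intron_type == "minor" else "minor"
    retained = int((focal_state == intron_type).sum())
    converted = int((focal_state == other_type).sum())
    deleted = int((focal_state == "absent").sum())
    return {
        "n_ancestral": n,
        "retained": retained / n,
        "converted": converted / n,
        "deleted": deleted / n,
    }
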