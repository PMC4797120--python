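"""Alpha-diversity statistics for isolate-count vectors.

The survey summarizes each grouping (season, site or tissue marginal) by
eight numbers: total isolates S, species richness Np, the Gleason index
G = (Np - 1)/ln S and its relative form GR = (Np - 1)/S, Simpson's
dominance D = sum p_i^2 with its complement 1 - D, the Shannon-Wiener
entropy H' = -sum p_i ln p_i (in nats), and Pielou's evenness
E = H'/ln Np.  ``diversity_profile`` assembles one such row from a
single abundance vector; ``diversity_table`` builds the whole summary
for one factor of a survey.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .data import (
    AbundanceVector,
    CFMatrix,
    SegmentDesign,
    marginalize,
)

__all__ = [
    "DiversityRow",
    "colonization_frequency",
    "species_richness",
    "gleason",
    "relative_gleason",
    "simpson_dominance",
    "simpson_diversity",
    "shannon",
    "pielou",
    "diversity_profile",
    "diversity_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (2.3445 -> 2.345), as display tables do.

    Python's built-in round is banker's rounding, which disagrees with
    the printed tables on exact .5 boundaries.
    """
    scale = 10**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass
class DiversityRow:
    """One grouping's alpha-diversity summary (full precision)."""

    label: str
    S: int
    Np: int
    G: float
    GR: float
    D: float
    one_minus_D: float
    H: float
    E: float
    evenness_defined: bool = True  # False for single-species groupings

    def rounded(self) -> dict[str, object]:
        """Display form: indices at 3 dp, evenness at 2 dp."""
        return {
            "label": self.label,
            "S": self.S,
            "Np": self.Np,
            "G": round_half_up(self.G, 3),
            "GR": round_half_up(self.GR, 3),
            "D": round_half_up(self.D, 3),
            "1-D": round_half_up(self.one_minus_D, 3),
            "H": round_half_up(self.H, 3),
            "E": round_half_up(self.E, 2),
        }


def colonization_frequency(colonized_segments: int, total_segments: int) -> float:
    """Percent of incubated segments colonized by one endophyte."""
    if total_segments < 1:
        raise ValueError("total_segments must be >= 1")
    if colonized_segments < 0:
        raise ValueError("colonized_segments must be >= 0")
    if colonized_segments > total_segments:
        raise ValueError(
            f"colonized segments ({colonized_segments}) exceed total ({total_segments})"
        )
    return colonized_segments / total_segments * 100


def species_richness(a: AbundanceVector) -> int:
    """Number of species with at least one isolate (Np)."""
    return sum(1 for c in a.counts.values() if c > 0)


def gleason(richness: int, n_isolates: int) -> float:
    """Gleason richness index G = (Np - 1) / ln S."""
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if n_isolates < 2:
        raise ValueError("Gleason index needs n_isolates >= 2 (ln S must be positive)")
    return (richness - 1) / math.log(n_isolates)


def relative_gleason(richness: int, n_isolates: int) -> float:
    """Relative Gleason index GR = (Np - 1) / S."""
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if n_isolates < 1:
        raise ValueError("relative Gleason needs n_isolates >= 1")
    return (richness - 1) / n_isolates


def _proportions(a: AbundanceVector) -> list[float]:
    total = a.total
    if total <= 0:
        raise ValueError("abundance vector has no isolates")
    return [c / total for c in a.counts.values() if c > 0]


def simpson_dominance(a: AbundanceVector) -> float:
    """Simpson dominance D = sum p_i^2, the same-species draw probability."""
    return sum(p * p for p in _proportions(a))


def simpson_diversity(D: float) -> float:
    """Simpson's index of diversity, the complement 1 - D."""
    if not 0 <= D <= 1:
        raise ValueError(f"Simpson dominance must lie in [0, 1], got {D}")
    return 1 - D


def shannon(a: AbundanceVector) -> float:
    """Shannon-Wiener entropy H' = -sum p_i ln p_i, in nats."""
    return -sum(p * math.log(p) for p in _proportions(a))


def pielou(H: float, richness: int) -> float:
    """Pielou's evenness E = H' / ln Np."""
    if richness < 2:
        raise ValueError("Pielou evenness is undefined for richness < 2")
    if H < 0:
        raise ValueError("Shannon entropy cannot be negative")
    E = H / math.log(richness)
    if E > 1 + 1e-12:
        warnings.warn(
            f"evenness {E:.4f} > 1: H exceeds ln(richness); check inputs",
            stacklevel=2,
        )
    return E


def diversity_profile(a: AbundanceVector, label: str = "") -> DiversityRow:
    """All eight summary statistics from one abundance vector.

    A single-species vector has no defined evenness; by convention it is
    reported as E = 1 (a one-species community is trivially even) with
    ``evenness_defined=False``.
    """
    S = a.total
    if S <= 0:
        raise ValueError("abundance vector has no isolates")
    Np = species_richness(a)
    D = simpson_dominance(a)
    H = shannon(a)
    if Np >= 2:
        G = gleason(Np, S) if S >= 2 else 0.0
        E = pielou(H, Np)
        defined = True
    else:
        G = 0.0
        E = 1.0
        defined = False
    return DiversityRow(
        label=label or a.label,
        S=S,
        Np=Np,
        G=G,
        GR=relative_gleason(Np, S),
        D=D,
        one_minus_D=simpson_diversity(D),
        H=H,
        E=E,
        evenness_defined=defined,
    )


def diversity_table(
    data: CFMatrix | pd.DataFrame,
    by: str,
    design: SegmentDesign = SegmentDesign(),
    rounded: bool = True,
) -> pd.DataFrame:
    """Per-level diversity summary for one factor of a survey.

    Marginalizes the survey over the other two factors, then profiles
    each level.  Column order matches the survey's printed summary
    (label, S, Np, G, GR, D, 1-D, H, E).
    """
    rows = []
    for level, vec in marginalize(data, by, design).items():
        profile = diversity_profile(vec, label=str(level))
        if rounded:
            rows.append(profile.rounded())
        else:
            rows.append(
                {
                    "label": profile.label,
                    "S": profile.S,
                    "Np": profile.Np,
                    "G": profile.G,
                    "GR": profile.GR,
                    "D": profile.D,
                    "1-D": profile.one_minus_D,
                    "H": profile.H,
                    "E": profile.E,
                }
            )
    return pd.DataFrame(rows)
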