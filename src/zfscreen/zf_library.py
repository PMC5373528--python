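"""Combinatorics of the 3F zinc-finger library and target-site statistics.

Sixteen zinc-finger modules each bind one 5'-GNN-3' DNA triplet, so ordered
arrays of three fingers (3Fs) span 16^3 = 4096 combinations, each predicted
to recognize one 9-bp site.  The library is organized as subpools sharing a
first-cloned "founder" finger, hence at most 256 arrays per subpool; the
pool founded on the GAA-binding finger proved unstable and was never
constructed.

An exact 9-bp site, counting both strands, recurs once per 4^9/2 = 131072
bp of random equiprobable DNA — the "once in ~130,000 bp" rule of thumb —
giving on the order of a thousand expected occurrences in a 1.3x10^8-bp
genome.  These expectations are linear approximations ignoring word
self-overlap, adequate at genomic scales.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from zfscreen.scanner import DegeneratePattern, SITE_LENGTH

_BASES = "ACGT"

GAA_FOUNDER = "GAA"  # the one subpool founder whose pool was never constructed


@dataclass(frozen=True)
class FingerCode:
    """One zinc-finger module, identified by the GNN triplet it binds."""

    triplet: str
    name: str = ""

    def __post_init__(self) -> None:
        t = self.triplet.upper()
        if len(t) != 3 or t[0] != "G" or any(b not in _BASES for b in t):
            raise ValueError(
                f"finger triplet must be a 5'-GNN-3' DNA word, got {self.triplet!r}"
            )
        object.__setattr__(self, "triplet", t)
        if not self.name:
            object.__setattr__(self, "name", f"ZF-{t}")


@dataclass(frozen=True)
class ThreeFingerArray:
    """An ordered triple of finger modules; position 1 is the founder."""

    fingers: tuple[FingerCode, FingerCode, FingerCode]
    pool_id: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.fingers) != 3:
            raise ValueError("a 3F array has exactly three fingers")

    @property
    def site(self) -> str:
        return predict_site(self)

    def __str__(self) -> str:
        return "-".join(f.triplet for f in self.fingers)


@dataclass(frozen=True)
class SubpoolSpec:
    """One founder-defined library subpool (at most 256 member arrays)."""

    pool_id: int
    founder: FingerCode
    constructed: bool = True
    nominal_size: int = 256

    def __post_init__(self) -> None:
        if self.nominal_size > 256:
            raise ValueError("a subpool holds at most 16^2 = 256 arrays")


def enumerate_fingers() -> List[FingerCode]:
    """The sixteen GNN-binding finger modules in lexicographic triplet order."""
    return [
        FingerCode("G" + n1 + n2)
        for n1, n2 in itertools.product(_BASES, repeat=2)
    ]


def _as_finger(finger: Union[FingerCode, str]) -> FingerCode:
    if isinstance(finger, FingerCode):
        return finger
    return FingerCode(str(finger))


def enumerate_library(
    founder: Optional[Union[FingerCode, str]] = None
) -> List[ThreeFingerArray]:
    """All 16^3 = 4096 ordered 3F arrays, or one founder's 256-array subpool.

    ``founder``, if given, restricts position 1 to that finger and must be
    one of the sixteen GNN triplets.
    """
    fingers = enumerate_fingers()
    if founder is not None:
        founder = _as_finger(founder)
        if founder.triplet not in {f.triplet for f in fingers}:
            raise ValueError(f"unknown founder triplet {founder.triplet!r}")
        firsts: Sequence[FingerCode] = [founder]
    else:
        firsts = fingers
    pool_ids = {f.triplet: i + 1 for i, f in enumerate(fingers)}
    return [
        ThreeFingerArray(fingers=(f1, f2, f3), pool_id=pool_ids[f1.triplet])
        for f1 in firsts
        for f2 in fingers
        for f3 in fingers
    ]


def default_subpools() -> List[SubpoolSpec]:
    """The sixteen founder subpools; the GAA pool is flagged not constructed."""
    return [
        SubpoolSpec(
            pool_id=i + 1,
            founder=f,
            constructed=f.triplet != GAA_FOUNDER,
        )
        for i, f in enumerate(enumerate_fingers())
    ]


def predict_site(array: ThreeFingerArray, orientation: str = "as_printed") -> str:
    """Predicted 9-bp recognition site of a 3F array.

    ``orientation='as_printed'`` concatenates position 1's triplet leftmost
    (5'), matching how screen isolates' sites are conventionally written
    (e.g. fingers GGT, GAT, GGA give "GGTGATGGA").  ``orientation=
    'reversed'`` models the alternative polarity in which the first finger
    binds the 3'-most triplet.
    """
    triplets = [f.triplet for f in array.fingers]
    if orientation == "as_printed":
        return "".join(triplets)
    if orientation == "reversed":
        return "".join(reversed(triplets))
    raise ValueError(f"unknown orientation {orientation!r}")


def base_probs_from_gc(gc_content: float) -> np.ndarray:
    """(A, C, G, T) probabilities for a given GC fraction, strand-symmetric."""
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return np.array([at, gc, gc, at])


def expected_site_spacing(
    pattern: DegeneratePattern,
    base_probs: Optional[Sequence[float]] = None,
    strands: int = 2,
) -> float:
    """Expected bp of random DNA per pattern hit, counting both strands.

    The reciprocal of the per-window expected strand-hit rate.  For an
    exact 9-mer under equiprobable bases this is 4^9/2 = 131072 bp,
    i.e. one site per ~130,000 bp of genomic DNA.
    """
    p = pattern.match_probability(base_probs, strands=strands)
    if p <= 0:
        raise ValueError("pattern has zero match probability")
    return 1.0 / p


def expected_genome_occurrences(
    pattern: DegeneratePattern,
    genome_length: float,
    base_probs: Optional[Sequence[float]] = None,
    strands: int = 2,
) -> float:
    """Expected pattern hit count in a random genome of the given length.

    Linear approximation: (genome_length - 8) windows times the per-window
    double-stranded match probability, ignoring overlap corrections.  For
    an exact 9-mer in 1.3x10^8 bp of equiprobable DNA this is ~992, the
    "approximately 1000 occurrences" expectation for an Arabidopsis-sized
    genome.  Returns 0 when no 9-bp window fits.
    """
    if genome_length < SITE_LENGTH:
        return 0.0
    n_windows = genome_length - (SITE_LENGTH - 1)
    return n_windows * pattern.match_probability(base_probs, strands=strands)


def library_table(arrays: Optional[Sequence[ThreeFingerArray]] = None):
    """Library specification as a DataFrame (pool_id, founder, fingers, site)."""
    import pandas as pd

    if arrays is None:
        arrays = enumerate_library()
    return pd.DataFrame(
        {
            "pool_id": [a.pool_id for a in arrays],
            "founder": [a.fingers[0].triplet for a in arrays],
            "finger1": [a.fingers[0].triplet for a in arrays],
            "finger2": [a.fingers[1].triplet for a in arrays],
            "finger3": [a.fingers[2].triplet for a in arrays],
            "site": [a.site for a in arrays],
        }
    )
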