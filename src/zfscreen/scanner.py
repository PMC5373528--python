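"""Degenerate 9-bp recognition-site scanning and promoter enrichment.

A 3F zinc-finger array recognizes a 9-bp site composed of three 5'-GNN-3'
triplets.  Site searches in promoter sets allow a per-triplet mismatch
budget at the two N positions of each triplet; the G anchors (offsets 0, 3
and 6 of the site) must always match exactly.  A pattern therefore matches
1, 343 (= 7^3) or 4096 (= 16^3) distinct 9-mers at allowances 0, 1 and 2.

Scanning is double-stranded: a window is reported on the minus strand when
its reverse complement matches the pattern.  Offsets are always given on
the forward coordinate system, 0-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

SITE_LENGTH = 9
ANCHOR_OFFSETS = (0, 3, 6)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric encoding used by the vectorized scanner; N = 4 never equals a base
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string over {A, C, G, T, N}."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate_site(site: str) -> str:
    site = site.upper().replace("-", "")
    if len(site) != SITE_LENGTH:
        raise ValueError(f"site must be 9 bp, got {len(site)} bp: {site!r}")
    if any(b not in _BASES for b in site):
        raise ValueError(f"site contains non-ACGT characters: {site!r}")
    for off in ANCHOR_OFFSETS:
        if site[off] != "G":
            raise ValueError(
                f"site {site!r} is not a GNN-GNN-GNN word: anchor at offset "
                f"{off} is {site[off]!r}, expected 'G'"
            )
    return site


@dataclass(frozen=True)
class DegeneratePattern:
    """A 9-bp GNN-GNN-GNN site with a per-triplet mismatch allowance.

    Parameters
    ----------
    site
        The 9-bp consensus recognition site.
    n_mismatch_per_triplet
        Number of mismatches tolerated at the two N positions of *each*
        triplet (0, 1 or 2).  G anchors are always exact.
    """

    site: str
    n_mismatch_per_triplet: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", _validate_site(self.site))
        if not 0 <= self.n_mismatch_per_triplet <= 2:
            raise ValueError(
                "n_mismatch_per_triplet must be 0, 1 or 2, got "
                f"{self.n_mismatch_per_triplet}"
            )

    @property
    def triplets(self) -> tuple[str, str, str]:
        s = self.site
        return (s[0:3], s[3:6], s[6:9])

    def matching_words(self) -> List[str]:
        """All 9-mers matched by this pattern (1, 343 or 4096 words)."""
        allowance = self.n_mismatch_per_triplet
        per_triplet: List[List[str]] = []
        for trip in self.triplets:
            variants = []
            for n1, n2 in itertools.product(_BASES, repeat=2):
                mm = (n1 != trip[1]) + (n2 != trip[2])
                if mm <= allowance:
                    variants.append("G" + n1 + n2)
            per_triplet.append(variants)
        return ["".join(ws) for ws in itertools.product(*per_triplet)]

    def n_matching_words(self) -> int:
        per_triplet = {0: 1, 1: 7, 2: 16}[self.n_mismatch_per_triplet]
        return per_triplet ** 3

    def match_probability(
        self, base_probs: Optional[Sequence[float]] = None, strands: int = 2
    ) -> float:
        """Probability that a random 9-bp window matches the pattern.

        ``base_probs`` is the (A, C, G, T) composition of the background
        sequence; default equiprobable.  With ``strands=2`` the value is the
        expected number of *strand hits* per window, i.e. the sum of the
        forward-match and reverse-complement-match probabilities (a window
        matching on both strands contributes two hits, as the scanner
        reports one hit per strand).
        """
        if base_probs is None:
            base_probs = (0.25, 0.25, 0.25, 0.25)
        p = np.asarray(base_probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("base_probs must be 4 non-negative values summing to 1")
        if strands not in (1, 2):
            raise ValueError("strands must be 1 or 2")
        idx = {b: i for i, b in enumerate(_BASES)}

        def word_set_prob(words: Iterable[str]) -> float:
            return float(sum(np.prod([p[idx[b]] for b in w]) for w in words))

        words = self.matching_words()
        prob = word_set_prob(words)
        if strands == 2:
            prob += word_set_prob(reverse_complement(w) for w in words)
        return prob


def compile_pattern(site: str, allowance: int = 0) -> DegeneratePattern:
    """Compile a 9-bp GNN-GNN-GNN site into a scannable degenerate pattern.

    Raises ``ValueError`` for a site whose anchors (offsets 0, 3, 6) are not
    'G' or for an allowance outside 0-2.
    """
    return DegeneratePattern(site=site, n_mismatch_per_triplet=allowance)


@dataclass(frozen=True)
class ScanHit:
    """One pattern match: forward-coordinate offset, strand, mismatch use."""

    sequence_id: str
    offset: int
    strand: str  # '+' or '-'
    mismatches_used: tuple[int, int, int] = (0, 0, 0)

    @property
    def end(self) -> int:
        return self.offset + SITE_LENGTH


@dataclass
class EnrichmentResult:
    """Outcome of a promoter site-enrichment test."""

    observed_hits: int
    expected_hits: float
    binomial_p: float
    permutation_p: Optional[float] = None
    n_permutations: int = 0


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _strand_scan(codes: np.ndarray, pattern: DegeneratePattern):
    """Offsets and per-triplet mismatch counts of forward-strand matches."""
    n = codes.size - SITE_LENGTH + 1
    if n <= 0:
        return np.empty(0, dtype=np.intp), np.empty((0, 3), dtype=np.int8)
    site_codes = _CODE[np.frombuffer(pattern.site.encode("ascii"), dtype=np.uint8)]
    ok = np.ones(n, dtype=bool)
    mismatch = np.zeros((n, 3), dtype=np.int8)
    for off in range(SITE_LENGTH):
        col = codes[off : off + n]
        if off in ANCHOR_OFFSETS:
            ok &= col == site_codes[off]  # 'N' (code 4) never matches an anchor
        else:
            mismatch[:, off // 3] += (col != site_codes[off]).astype(np.int8)
    ok &= (mismatch <= pattern.n_mismatch_per_triplet).all(axis=1)
    idx = np.flatnonzero(ok)
    return idx, mismatch[idx]


def scan_sequence(
    sequence: str, pattern: DegeneratePattern, sequence_id: str = ""
) -> List[ScanHit]:
    """Find all pattern matches in ``sequence`` on both strands.

    Forward-strand windows matching the pattern are reported as '+' hits;
    windows whose reverse complement matches as '-' hits, both at their
    forward-coordinate offset.  Overlapping matches are all reported, and a
    window matching on both strands yields one hit per strand.  'N' bases
    never match a G anchor and count as mismatches at N positions.
    """
    if len(sequence) < SITE_LENGTH:
        return []
    codes = _encode(sequence)
    hits: List[ScanHit] = []
    fwd_idx, fwd_mm = _strand_scan(codes, pattern)
    for off, mm in zip(fwd_idx, fwd_mm):
        hits.append(ScanHit(sequence_id, int(off), "+", tuple(int(x) for x in mm)))
    rc_codes = _RC_CODE[codes[::-1]]
    rev_idx, rev_mm = _strand_scan(rc_codes, pattern)
    L = codes.size
    for off, mm in zip(rev_idx, rev_mm):
        hits.append(
            ScanHit(
                sequence_id,
                int(L - SITE_LENGTH - off),
                "-",
                tuple(int(x) for x in mm),
            )
        )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def count_in_promoters(
    promoters: Mapping[str, str],
    pattern: DegeneratePattern,
    allow_empty: bool = False,
) -> tuple[int, Dict[str, int]]:
    """Total and per-gene pattern hit counts over a promoter set.

    ``promoters`` maps gene id to promoter sequence (conventionally the
    1000 bp upstream of the annotated start).  Raises on an empty set
    unless ``allow_empty`` is set.
    """
    if not promoters and not allow_empty:
        raise ValueError("promoter set is empty (pass allow_empty=True to permit)")
    per_gene = {
        gene: len(scan_sequence(seq, pattern, sequence_id=gene))
        for gene, seq in promoters.items()
    }
    return sum(per_gene.values()), per_gene


def base_composition(sequences: Iterable[str]) -> np.ndarray:
    """(A, C, G, T) frequencies over a collection of sequences, ignoring N."""
    counts = np.zeros(4, dtype=float)
    for seq in sequences:
        codes = _encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T bases in the sequence collection")
    return counts / total


def enrichment_test(
    target_genes: Iterable[str],
    universe: Mapping[str, str],
    pattern: DegeneratePattern,
    null: str = "binomial",
    n_permutations: int = 1000,
    seed: Optional[int] = None,
) -> EnrichmentResult:
    """Test a gene set's promoters for recognition-site enrichment.

    The binomial null treats every 9-bp window of the target promoters as
    an independent Bernoulli trial with the pattern's double-stranded match
    probability under the universe's base composition, and reports the
    upper-tail probability of the observed hit total.  The permutation null
    draws equally sized gene sets uniformly from the universe and reports
    the upper-tail fraction with a (r + 1)/(n + 1) pseudocount.  With
    ``null='permutation'`` both p-values are computed.
    """
    target = list(dict.fromkeys(target_genes))
    if not target:
        raise ValueError("target gene set is empty")
    missing = [g for g in target if g not in universe]
    if missing:
        raise KeyError(f"target genes absent from universe: {missing[:5]}")
    if null not in ("binomial", "permutation"):
        raise ValueError(f"unknown null model: {null!r}")

    _, per_gene = count_in_promoters(universe, pattern)
    observed = sum(per_gene[g] for g in target)

    comp = base_composition(universe.values())
    p_window = pattern.match_probability(comp, strands=2)
    n_windows = sum(
        max(len(universe[g]) - SITE_LENGTH + 1, 0) for g in target
    )
    expected = n_windows * p_window
    # expected strand hits per window may exceed 1 only for absurdly
    # degenerate patterns; binomial on windows is the intended null
    binom_p = float(stats.binom.sf(observed - 1, n_windows, min(p_window, 1.0)))

    perm_p = None
    if null == "permutation":
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        gene_ids = np.array(list(universe.keys()))
        counts_arr = np.array([per_gene[g] for g in gene_ids])
        k = len(target)
        totals = np.empty(n_permutations, dtype=np.int64)
        for i in range(n_permutations):
            pick = rng.choice(counts_arr.size, size=k, replace=False)
            totals[i] = counts_arr[pick].sum()
        r = int((totals >= observed).sum())
        perm_p = (r + 1) / (n_permutations + 1)

    return EnrichmentResult(
        observed_hits=int(observed),
        expected_hits=float(expected),
        binomial_p=binom_p,
        permutation_p=perm_p,
        n_permutations=n_permutations if null == "permutation" else 0,
    )


def extract_promoters(
    genome: Mapping[str, str],
    intervals: Sequence[tuple],
    length: int = 1000,
) -> Dict[str, str]:
    """Extract upstream promoter windows from a genome.

    ``intervals`` holds BED-like records ``(chrom, start, end, gene_id,
    strand)`` with 0-based half-open gene coordinates.  For a '+' gene the
    promoter is the ``length`` bp ending at ``start``; for a '-' gene the
    reverse complement of the ``length`` bp starting at ``end``.  Windows
    are clipped at chromosome bounds.
    """
    promoters: Dict[str, str] = {}
    for chrom, start, end, gene_id, strand in intervals:
        seq = genome[chrom]
        if strand == "+":
            window = seq[max(start - length, 0) : start]
        elif strand == "-":
            window = reverse_complement(seq[end : end + length])
        else:
            raise ValueError(f"invalid strand {strand!r} for {gene_id}")
        promoters[gene_id] = window.upper()
    return promoters
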