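"""Seeded generators for every input the analysis consumes.

Each generator is a pure function of its parameters and a seed: the same
call yields bit-identical data.  The generated structure mirrors the
statistical assumptions of a ZF-ATF screen —

- promoters: i.i.d. random DNA at a controlled base composition, with an
  exact copy of a 9-bp recognition site planted at a controlled
  per-promoter rate;
- counts: negative-binomial gene x sample matrices with log-normal
  baseline means, per-line planted DEG sets, and a "background" DEG set
  shared by every line of one effector class (including its background
  pool), emulating effector-generic transcriptional responses;
- growth: exponential rosette-area trajectories with multiplicative
  log-normal noise.

Ground truth (planted positions, DEG sets, true rates, parameters, seed)
travels alongside every dataset in a :class:`SimulationTruth`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from zfscreen.scanner import DegeneratePattern, SITE_LENGTH, reverse_complement
from zfscreen.transcriptomics import CountMatrix
from zfscreen.zf_library import base_probs_from_gc

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth recorded with every generated dataset."""

    generator: str
    parameters: Dict
    seed: int
    planted_sites: Dict[str, List[Dict]] = field(default_factory=dict)
    line_specific_degs: Dict[str, List[str]] = field(default_factory=dict)
    background_degs: List[str] = field(default_factory=list)
    true_log2fc: Dict[str, Dict[str, float]] = field(default_factory=dict)
    true_growth_rates: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        return cls(**json.loads(text))


def simulate_promoters(
    n_genes: int,
    length: int = 1000,
    gc_content: float = 0.5,
    pattern: Optional[DegeneratePattern] = None,
    planting_rate: float = 0.0,
    seed: int = 0,
) -> Tuple[Dict[str, str], SimulationTruth]:
    """Random promoter set with optionally planted recognition sites.

    Bases are drawn i.i.d. at the composition implied by ``gc_content``.
    With probability ``planting_rate`` per promoter, one exact copy of the
    pattern's consensus site replaces a uniformly chosen window, on a
    uniformly chosen strand.  Truth records each placement.
    """
    if not 0.0 <= planting_rate <= 1.0:
        raise ValueError("planting_rate must lie in [0, 1]")
    if planting_rate > 0 and (pattern is None or length < SITE_LENGTH):
        raise ValueError(
            "planting requires a pattern and promoter length >= 9 bp"
        )
    rng = np.random.default_rng(seed)
    probs = base_probs_from_gc(gc_content)
    promoters: Dict[str, str] = {}
    truth = SimulationTruth(
        generator="simulate_promoters",
        parameters={
            "n_genes": n_genes,
            "length": length,
            "gc_content": gc_content,
            "site": pattern.site if pattern else None,
            "planting_rate": planting_rate,
        },
        seed=seed,
    )
    for i in range(n_genes):
        gene = f"gene{i + 1:05d}"
        seq = rng.choice(_BASES, size=length, p=probs)
        if planting_rate > 0 and rng.random() < planting_rate:
            pos = int(rng.integers(0, length - SITE_LENGTH + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            word = pattern.site if strand == "+" else reverse_complement(pattern.site)
            seq[pos : pos + SITE_LENGTH] = list(word)
            truth.planted_sites[gene] = [
                {"offset": pos, "strand": strand, "site": pattern.site}
            ]
        promoters[gene] = "".join(seq)
    return promoters, truth


def simulate_counts(
    n_genes: int = 2000,
    lines: Sequence[str] = ("line1", "line2", "line3"),
    n_reps: int = 3,
    baseline_log_mean: float = np.log(100.0),
    baseline_log_sd: float = 1.5,
    dispersion: float = 0.05,
    line_specific_deg_fraction: float = 0.02,
    background_deg_fraction: float = 0.05,
    log2fc: float = 2.0,
    control: str = "Col-0",
    background_pool: Optional[str] = "background",
    depth_cv: float = 0.1,
    seed: int = 0,
) -> Tuple[CountMatrix, pd.Series, SimulationTruth]:
    """Negative-binomial count matrix with planted differential expression.

    Per-gene baseline means follow a log-normal law (default median 100,
    log-sd 1.5 — a realistic dynamic range with a low-expression shoulder).
    Each line carries its own planted DEG set at ``log2fc`` (random sign);
    a disjoint background DEG set is shared by *all* lines and by the
    background pool, emulating the effector-generic response that
    background subtraction is designed to remove.  Sample depths vary
    log-normally with coefficient of variation ``depth_cv``.  Counts are
    NB with the given dispersion (variance m + phi m^2).

    Returns (CountMatrix, gene lengths in kbp, truth).  Truth records the
    per-line specific DEG ids, the shared background DEG ids, and every
    true log2 fold change.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    total_frac = line_specific_deg_fraction * len(lines) + background_deg_fraction
    if total_frac > 1:
        raise ValueError("DEG fractions exceed the gene count")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)
    lengths = pd.Series(
        rng.lognormal(np.log(1.5), 0.4, size=n_genes), index=genes,
        name="length_kbp",
    )

    n_line_specific = int(round(line_specific_deg_fraction * n_genes))
    n_background = int(round(background_deg_fraction * n_genes))
    perm = rng.permutation(n_genes)
    cursor = 0
    line_specific: Dict[str, np.ndarray] = {}
    for line in lines:
        line_specific[line] = perm[cursor : cursor + n_line_specific]
        cursor += n_line_specific
    background_idx = perm[cursor : cursor + n_background]

    groups: Dict[str, str] = {}
    data: Dict[str, np.ndarray] = {}
    truth = SimulationTruth(
        generator="simulate_counts",
        parameters={
            "n_genes": n_genes,
            "lines": list(lines),
            "n_reps": n_reps,
            "dispersion": dispersion,
            "line_specific_deg_fraction": line_specific_deg_fraction,
            "background_deg_fraction": background_deg_fraction,
            "log2fc": log2fc,
            "control": control,
            "background_pool": background_pool,
        },
        seed=seed,
    )
    truth.background_degs = [genes[i] for i in background_idx]

    # one shared sign/effect vector for the background response
    bg_signs = rng.choice([-1.0, 1.0], size=n_background)
    effects: Dict[str, np.ndarray] = {}
    group_names = [control] + list(lines)
    if background_pool is not None:
        group_names.append(background_pool)
    for group in group_names:
        lfc = np.zeros(n_genes)
        if group != control:
            lfc[background_idx] = bg_signs * log2fc
        if group in line_specific:
            idx = line_specific[group]
            signs = rng.choice([-1.0, 1.0], size=idx.size)
            lfc[idx] = signs * log2fc
            truth.line_specific_degs[group] = [genes[i] for i in idx]
        effects[group] = lfc
        truth.true_log2fc[group] = {
            genes[i]: float(lfc[i]) for i in np.flatnonzero(lfc)
        }

    r = 1.0 / dispersion
    for group in group_names:
        mu_group = baseline * np.exp2(effects[group])
        for rep in range(1, n_reps + 1):
            depth = rng.lognormal(0.0, depth_cv) if depth_cv > 0 else 1.0
            mu = mu_group * depth
            sample = f"{group}_r{rep}"
            data[sample] = rng.negative_binomial(r, r / (r + mu))
            groups[sample] = group

    counts = pd.DataFrame(data, index=genes)
    cm = CountMatrix(counts=counts, groups=pd.Series(groups))
    return cm, lengths, truth


def simulate_growth(
    genotype_rates: Mapping[str, float],
    n_plants: int = 7,
    days: Sequence[int] = tuple(range(10, 29, 3)),
    initial_area: float = 50.0,
    initial_area_scale: Optional[Mapping[str, float]] = None,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> Tuple[pd.DataFrame, SimulationTruth]:
    """Exponential rosette-growth trajectories with multiplicative noise.

    Each plant's area follows A0 * exp(rgr * day) * lognormal(0, sigma)
    where sigma gives the requested coefficient of variation.  Sampling
    days default to every 3 days from 10 to 28 dpg, the standard
    phenotyping window.  ``initial_area_scale`` scales A0 per genotype
    (e.g. 1.55 makes a genotype's relative RSA ~155% at every day when its
    rate equals the control's).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    rows = []
    for genotype, rate in genotype_rates.items():
        scale = 1.0 if initial_area_scale is None else initial_area_scale.get(
            genotype, 1.0
        )
        for p in range(1, n_plants + 1):
            plant_id = f"{genotype}_p{p:03d}"
            for day in days:
                noise = rng.lognormal(0.0, sigma) if noise_cv > 0 else 1.0
                area = initial_area * scale * np.exp(rate * day) * noise
                rows.append(
                    {
                        "plant_id": plant_id,
                        "genotype": genotype,
                        "day": int(day),
                        "area": float(area),
                    }
                )
    table = pd.DataFrame(rows, columns=["plant_id", "genotype", "day", "area"])
    truth = SimulationTruth(
        generator="simulate_growth",
        parameters={
            "n_plants": n_plants,
            "days": [int(d) for d in days],
            "initial_area": initial_area,
            "noise_cv": noise_cv,
        },
        seed=seed,
        true_growth_rates={g: float(r) for g, r in genotype_rates.items()},
    )
    return table, truth
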