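"""End-to-end orchestration of the transcriptomic + motif-scan analysis.

The pipeline reproduces the analysis order of a ZF-ATF screen on any input
(real tables or the seeded synthetic generators): normalize counts, filter
to actively expressed genes, test each selected line against the control,
adjust with Benjamini-Hochberg and call DEGs, partition DEG sets across
lines (Venn), subtract the background pool's DEGs, test label-based
category enrichment, and scan the DEG promoters for the line's predicted
recognition site against binomial and permutation nulls.

Configuration is a flat YAML mapping validated against a fixed key set;
every run writes a manifest recording parameters, seed and output
checksums so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from zfscreen import io as zio
from zfscreen import scanner, simulate, transcriptomics as tx

logger = logging.getLogger("zfscreen")

_CONFIG_DEFAULTS = {
    # inputs: either file paths or a synthetic block
    "counts": None,
    "samples": None,
    "annotation": None,
    "promoters": None,
    "synthetic": None,  # mapping of simulate_counts/simulate_promoters kwargs
    # stage parameters
    "control_group": "Col-0",
    "lines": None,  # list; default = all non-control, non-background groups
    "background_groups": [],
    "alpha": 1e-4,
    "min_fold": None,
    "z_min": -3.0,
    "active_filter": True,
    "site": None,  # 9-bp recognition site to scan DEG promoters for
    "allowance": 0,
    "n_permutations": 1000,
    "enrichment_label": None,  # boolean annotation column for enrichment
    "seed": 0,
    "outdir": "zfscreen_out",
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    values: Dict

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        unknown = set(raw) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values = dict(_CONFIG_DEFAULTS)
        values.update(raw)
        return cls(values=values)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)

    def __getitem__(self, key):
        return self.values[key]

    @property
    def hash(self) -> str:
        # outdir does not influence any computed result
        values = {k: v for k, v in self.values.items() if k != "outdir"}
        blob = json.dumps(values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _load_inputs(config: PipelineConfig):
    if config["synthetic"] is not None:
        syn = dict(config["synthetic"])
        counts_kwargs = dict(syn.get("counts", {}))
        counts_kwargs.setdefault("seed", config["seed"])
        cm, lengths, truth = simulate.simulate_counts(**counts_kwargs)
        annotation = pd.DataFrame({"length_kbp": lengths})
        promoters = None
        if "promoters" in syn:
            pk = dict(syn["promoters"])
            pk.setdefault("seed", config["seed"] + 1)
            plant_in = pk.pop("plant_in_truth_of", None)
            site = pk.pop("site", None)
            if site is not None:
                pk["pattern"] = scanner.compile_pattern(
                    site, pk.pop("allowance", 0)
                )
            promoters, _ = simulate.simulate_promoters(**pk)
            if plant_in is not None:
                # plant one exact site in each true DEG promoter of a line,
                # to exercise the positive-enrichment path end to end
                if site is None:
                    raise ValueError("plant_in_truth_of requires a site")
                rng = np.random.default_rng(config["seed"] + 2)
                for gene in truth.line_specific_degs.get(plant_in, []):
                    if gene in promoters:
                        seq = promoters[gene]
                        pos = int(rng.integers(0, len(seq) - scanner.SITE_LENGTH + 1))
                        promoters[gene] = (
                            seq[:pos] + site + seq[pos + scanner.SITE_LENGTH :]
                        )
        return cm, annotation, promoters, truth
    if not (config["counts"] and config["samples"] and config["annotation"]):
        raise ValueError(
            "config needs either a 'synthetic' block or counts/samples/annotation paths"
        )
    cm = zio.read_counts(config["counts"], config["samples"])
    annotation = zio.read_annotation(config["annotation"])
    promoters = (
        zio.read_fasta(config["promoters"]) if config["promoters"] else None
    )
    return cm, annotation, promoters, None


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run every analysis stage; returns the result bundle and writes outputs.

    Stage order: normalize -> active filter -> DE per line -> BH/call ->
    Venn + background subtraction -> category enrichment -> motif scan of
    specific-DEG promoters.  Deterministic given the config (all stochastic
    stages derive from the config seed).
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    cm, annotation, promoters, truth = _load_inputs(config)
    logger.info(
        "pipeline start: %d genes x %d samples, config %s",
        len(cm.genes), len(cm.samples), config.hash,
    )

    lengths = annotation["length_kbp"]
    size_factors = tx.estimate_size_factors(cm.counts)
    expr = tx.normalize(cm.counts, lengths, size_factors)

    if config["active_filter"]:
        active = tx.active_genes(expr, cm.groups, z_min=config["z_min"])
    else:
        active = pd.Series(True, index=cm.genes)
    active_counts = tx.CountMatrix(
        counts=cm.counts.loc[active], groups=cm.groups
    )
    logger.info("active genes: %d / %d", int(active.sum()), len(active))

    control = config["control_group"]
    backgrounds = list(config["background_groups"] or [])
    groups = list(pd.unique(cm.groups))
    lines = config["lines"] or [
        g for g in groups if g != control and g not in backgrounds
    ]

    deg_tables: Dict[str, pd.DataFrame] = {}
    deg_sets: Dict[str, set] = {}
    for group in lines + backgrounds:
        table = tx.de_test(active_counts, group, control)
        up, down = tx.call_degs(table, config["alpha"], config["min_fold"])
        deg_tables[group] = table
        deg_sets[group] = up | down
        table.to_csv(outdir / f"deg_{group}_vs_{control}.tsv", sep="\t")
        logger.info(
            "contrast %s vs %s: %d up, %d down", group, control, len(up), len(down)
        )

    results: Dict = {
        "config_hash": config.hash,
        "n_genes": int(len(cm.genes)),
        "n_active": int(active.sum()),
        "deg_counts": {g: len(s) for g, s in deg_sets.items()},
    }

    if len(deg_sets) >= 2:
        venn = tx.venn_partition(deg_sets)
        venn_df = pd.DataFrame(
            {
                "sets": ["&".join(sorted(k)) for k in venn],
                "count": list(venn.values()),
            }
        ).sort_values("sets")
        venn_df.to_csv(outdir / "venn_regions.tsv", sep="\t", index=False)
        results["venn"] = dict(zip(venn_df["sets"], venn_df["count"]))

    specific = tx.background_subtract(
        {g: deg_sets[g] for g in lines},
        {g: deg_sets[g] for g in backgrounds} or None,
    )
    results["specific_degs"] = sorted(specific)
    logger.info("line-specific DEGs after background subtraction: %d", len(specific))

    if config["enrichment_label"] and specific:
        labels = annotation[config["enrichment_label"]].astype(bool)
        frac, p = tx.category_enrichment(
            specific & set(active_counts.genes), labels.loc[active_counts.genes]
        )
        results["category_enrichment"] = {
            "label": config["enrichment_label"],
            "fraction": frac,
            "hypergeom_p": p,
        }

    if config["site"] and promoters is not None and specific:
        pattern = scanner.compile_pattern(config["site"], config["allowance"])
        target = [g for g in specific if g in promoters]
        if target:
            enr = scanner.enrichment_test(
                target,
                promoters,
                pattern,
                null="permutation",
                n_permutations=config["n_permutations"],
                seed=config["seed"] + 17,
            )
            results["site_enrichment"] = {
                "site": pattern.site,
                "allowance": pattern.n_mismatch_per_triplet,
                "observed_hits": enr.observed_hits,
                "expected_hits": enr.expected_hits,
                "binomial_p": enr.binomial_p,
                "permutation_p": enr.permutation_p,
            }
            logger.info(
                "site %s in %d specific-DEG promoters: %d hits (%.2f expected)",
                pattern.site, len(target), enr.observed_hits, enr.expected_hits,
            )

    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)

    manifest = {
        "config": config.values,
        "config_hash": config.hash,
        "outputs": {
            p.name: _file_checksum(p)
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return results
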