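"""Run the end-to-end pipeline on synthetic data from a config mapping.

One selected line plus a background pool; the line's true DEG promoters
carry planted copies of its predicted recognition site, so the final motif
stage should flag enrichment.  Outputs (DEG tables, Venn regions,
results.json, manifest.json) land in ./pipeline_out.
"""

import json

from zfscreen.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig.from_dict(
    {
        "synthetic": {
            "counts": {"n_genes": 800, "lines": ["line1"], "seed": 5},
            "promoters": {
                "n_genes": 800,
                "length": 1000,
                "site": "GGTGATGGA",
                "planting_rate": 0.0,
                "plant_in_truth_of": "line1",
                "seed": 6,
            },
        },
        "lines": ["line1"],
        "background_groups": ["background"],
        "site": "GGTGATGGA",
        "n_permutations": 500,
        "active_filter": True,
        "seed": 5,
        "outdir": "pipeline_out",
    }
)

results = run_pipeline(config)
print(json.dumps(results["deg_counts"], indent=2))
print(f"specific DEGs after background subtraction: {len(results['specific_degs'])}")
enr = results["site_enrichment"]
print(
    f"site {enr['site']} in specific-DEG promoters: {enr['observed_hits']} hits "
    f"(expected {enr['expected_hits']:.2f}), permutation p = {enr['permutation_p']}"
)
# planted sites in true DEG promoters make the motif stage light up; with
# planting disabled the same analysis reports frequencies consistent with
# random occurrence.
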