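"""Shared test utilities: run a synthetic bundle through the pipeline."""

import csv

from snvaa import fixtures, pipeline, variant_io


def run_bundle_pipeline(bundle, out_dir):
    """Write a bundle, run the pipeline end-to-end, and parse the output."""
    paths = fixtures.write_bundle(bundle, str(out_dir))
    cfg = variant_io.parse_config(paths["config"])
    final = pipeline.run_pipeline(cfg)
    with open(final, "rt", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = list(reader)
    return final, rows


def output_key(row):
    return (f"{row['Chromosome']}:{row['Variant Position']}:"
            f"{row['Ref nt']}:{row['Alt nt']}")
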