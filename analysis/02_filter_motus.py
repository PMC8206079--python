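"""Filter the raw MOTU read tables down to binary detection matrices.

Applies the fixed chain — negative-control removal, 96% similarity filter,
taxonomic-level assignment, per-taxon per-library 0.001 tag-jump filter,
1/0 binarization — and reports how many reads and MOTUs each step retained.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, YEARS, load_taxa_meta

from streamdna import io_schemas, motu_filtering as mf


def main() -> None:
    taxa_meta = load_taxa_meta()
    for year in YEARS:
        table = mf.read_motu_table(DATA_DIR / f"motus_{year}.tsv")
        samples = io_schemas.read_samples(DATA_DIR / f"samples_{year}.csv")
        raw = table.total_reads

        t = mf.remove_control_motus(table)
        t = mf.filter_similarity(t)
        t = mf.assign_reporting_level(t)
        t = mf.filter_tag_jumps(t)
        m = mf.to_detection_matrix(t, samples, taxa_meta=taxa_meta)

        io_schemas.write_detection_matrix(m, DATA_DIR / f"detections_{year}.tsv")
        pct = mf.percent_retained(raw, t.total_reads)
        print(f"{year}: {len(table.motus)} MOTUs / {raw:,} reads in -> "
              f"{len(t.motus)} MOTUs / {t.total_reads:,} reads out "
              f"({pct}% retained); {m.n_taxa} taxa x {m.n_units} samples, "
              f"{int(m.y.sum())} detections")


if __name__ == "__main__":
    main()
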