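"""Small bundled reference tables used for worked examples and regression
tests.

``ONCORHYNCHUS_CATEGORY_GENE_COUNTS`` holds published per-species gene
tallies by homology category for six Pacific salmon (*Oncorhynchus*)
species, classified against the unduplicated Northern pike outgroup after
the salmonid-specific whole-genome duplication. It is the canonical worked
example for :func:`wgdkit.classify.summary_from_category_gene_counts`.
"""

from __future__ import annotations

import pandas as pd

_CATEGORY_COLUMNS = ["contracting", "expanding", "singleton",
                     "resolving", "ohnolog", "paralog"]

ONCORHYNCHUS_CATEGORY_GENE_COUNTS = pd.DataFrame(
    [
        ("Oncorhynchus_gorbuscha",   652, 3220, 10012, 1092, 16382, 2158),
        ("Oncorhynchus_keta",        658,  566,  9208,  482, 11040,  658),
        ("Oncorhynchus_kisutch",     638, 2421,  9339, 1203, 19252, 1388),
        ("Oncorhynchus_mykiss",      633, 2238,  8990, 1222, 19696, 2168),
        ("Oncorhynchus_nerka",       764, 1679,  9969,  853, 14630, 2636),
        ("Oncorhynchus_tshawytscha", 661, 1927, 10157, 1215, 17670, 1478),
    ],
    columns=["species"] + _CATEGORY_COLUMNS,
).set_index("species")
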