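"""Published carrot MITE census used for worked-example arithmetic.

Reference numbers from the genome-wide annotation of MITEs in the carrot DH1
reference assembly (GCA_001625215.1): per-group family counts, copy counts,
occupied megabases and genomic-localization counts, plus occupied fractions
for eight other Asterid genomes annotated with the same pipeline. These serve
as inputs for summary arithmetic (genic fraction, mean element lengths,
genome fractions); nothing in the pipeline depends on them.
"""

from __future__ import annotations

import pandas as pd

from .genome_context import CATEGORIES

#: per-group census rows: families, copies, occupied Mbp, largest family,
#: localization counts (intergenic, upstream, 5'UTR, cds, intron, 3'UTR,
#: downstream)
CARROT_GROUPS: dict[str, dict] = {
    "hAT-like": dict(families=144, copies=3637, mbp=1.65, largest=217,
                     intergenic=1506, upstream=608, five_prime_utr=77,
                     cds=31, intron=918, three_prime_utr=66, downstream=431),
    "Mutator-like": dict(families=128, copies=6308, mbp=2.71, largest=542,
                         intergenic=3019, upstream=1148, five_prime_utr=52,
                         cds=12, intron=1343, three_prime_utr=58,
                         downstream=676),
    "Stowaway": dict(families=56, copies=11674, mbp=2.97, largest=1452,
                     intergenic=5605, upstream=2446, five_prime_utr=109,
                     cds=11, intron=1991, three_prime_utr=89, downstream=1423),
    "Tourist": dict(families=81, copies=8731, mbp=2.78, largest=1353,
                    intergenic=3867, upstream=1803, five_prime_utr=134,
                    cds=19, intron=1574, three_prime_utr=110, downstream=1224),
    "Unclassified": dict(families=19, copies=675, mbp=0.23, largest=141,
                         intergenic=335, upstream=99, five_prime_utr=5,
                         cds=2, intron=188, three_prime_utr=5, downstream=41),
}

#: carrot genome size in Mbp (published flow-cytometry size, not assembly span)
CARROT_GENOME_MBP = 473.0

#: occupied Mbp and genome size (Mbp) per Asterid species
ASTERID_OCCUPANCY: dict[str, tuple[float, float]] = {
    "carrot": (10.34, 473.0),
    "celery": (27.71, 3470.0),
    "pepper": (12.43, 3500.0),
    "coffee": (12.11, 1300.0),
    "fennel": (5.67, 1340.0),
    "sunflower": (73.28, 3500.0),
    "tomato": (7.07, 900.0),
    "potato": (7.65, 844.0),
}


def carrot_localization_table() -> pd.DataFrame:
    """Group x category localization table of the carrot census, with
    margins, in the layout produced by
    :func:`mitescape.genome_context.localization_table`."""
    rows = {}
    for group, d in CARROT_GROUPS.items():
        rows[group] = {cat: d[cat] for cat in CATEGORIES}
    table = pd.DataFrame.from_dict(rows, orient="index")[list(CATEGORIES)]
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table
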