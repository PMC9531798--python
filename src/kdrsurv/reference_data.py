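"""Published reference counts from the 2016 two-round kdr field survey.

These are the printed genotype and zygosity counts from a published
surveillance study of *Aedes aegypti* in southern Taiwan (two collection
rounds, March and October 2016, nine districts; 320 field males genotyped,
and 115 G1 females genotyped after a cypermethrin exposure bioassay).  They
ship with the package as the worked example: feeding them through the
package's statistics reproduces the study's published p-values, allele
frequencies and resistance-genotype classification, and they parameterise
the synthetic generator's March-like and October-like conditions.

Layouts:

* per-locus zygosity tables: ``{locus: {"wild"|"het"|"hom": (n_group1,
  n_group2)}}`` with groups (March, October) for the field survey and
  (dead, alive) for the bioassay;
* combined-genotype tables: ``{genotype_label: (n_group1, n_group2)}`` with
  alphabetically ordered haplotype pairs; the one genotype whose phase
  cannot be resolved under the six-haplotype panel appears in per-locus
  notation (``SP/VG/FC/DY``).
"""

from __future__ import annotations

__all__ = [
    "FIELD_GROUPS",
    "FIELD_LOCUS_COUNTS",
    "FIELD_GENOTYPE_COUNTS",
    "BIOASSAY_GROUPS",
    "BIOASSAY_LOCUS_COUNTS",
    "BIOASSAY_GENOTYPE_COUNTS",
    "WILD_GENOTYPE",
    "PUBLISHED_ALLELE_FREQS",
]

WILD_GENOTYPE = "SVFD/SVFD"

FIELD_GROUPS = ("March", "October")

#: Field survey, per-locus zygosity counts (March, October totals).
FIELD_LOCUS_COUNTS: dict[int, dict[str, tuple[int, int]]] = {
    989: {"wild": (127, 100), "het": (15, 45), "hom": (6, 27)},
    1016: {"wild": (108, 73), "het": (34, 59), "hom": (6, 40)},
    1534: {"wild": (103, 96), "het": (36, 59), "hom": (9, 17)},
    1763: {"wild": (139, 137), "het": (9, 31), "hom": (0, 4)},
}

#: Field survey, combined-genotype counts (March, October totals).
FIELD_GENOTYPE_COUNTS: dict[str, tuple[int, int]] = {
    "SVFD/SVFD": (72, 48),
    "SVCD/SVFD": (26, 8),
    "PGFD/SVFD": (10, 2),
    "SGFY/SVFD": (9, 4),
    "SGFD/SVCD": (6, 2),
    "SGFD/SVFD": (5, 2),
    "PVFD/SVFD": (1, 0),
    "SGFD/SGFY": (0, 1),
    "SP/VG/FC/DY": (0, 2),
    "PGFD/PGFY": (0, 2),
    "SGFY/SGFY": (0, 4),
    "SVCD/SVCD": (9, 17),
    "PGFD/SGFY": (0, 8),
    "SGFY/SVCD": (0, 14),
    "PGFD/PGFD": (6, 25),
    "PGFD/SVCD": (4, 33),
}

BIOASSAY_GROUPS = ("dead", "alive")

#: G1 bioassay, per-locus zygosity counts (dead, alive totals).
BIOASSAY_LOCUS_COUNTS: dict[int, dict[str, tuple[int, int]]] = {
    989: {"wild": (74, 12), "het": (4, 22), "hom": (0, 3)},
    1016: {"wild": (60, 3), "het": (18, 23), "hom": (0, 11)},
    1534: {"wild": (64, 16), "het": (12, 19), "hom": (2, 2)},
    1763: {"wild": (64, 25), "het": (14, 8), "hom": (0, 4)},
}

#: G1 bioassay, combined-genotype counts (dead, alive totals).
BIOASSAY_GENOTYPE_COUNTS: dict[str, tuple[int, int]] = {
    "SVFD/SVFD": (45, 0),
    "SVCD/SVFD": (12, 1),
    "SGFY/SVFD": (13, 0),
    "SVFD/SVFY": (1, 0),
    "SGFD/SVFD": (1, 1),
    "SVCD/SVCD": (2, 2),
    "PGFD/SVFD": (4, 4),
    "PGFD/SVCD": (0, 14),
    "SGFY/SVCD": (0, 4),
    "PGFD/SGFY": (0, 4),
    "SGFY/SGFY": (0, 4),
    "PGFD/PGFD": (0, 3),
}

#: Published headline mutant allele frequencies, by round then locus.
PUBLISHED_ALLELE_FREQS: dict[str, dict[int, float]] = {
    "March": {989: 0.09, 1016: 0.16, 1534: 0.18, 1763: 0.03},
    "October": {989: 0.29, 1016: 0.40, 1534: 0.27, 1763: 0.11},
}


def locus_counts_frame(counts: dict[int, dict[str, tuple[int, int]]],
                       groups: tuple[str, str]):
    """Tidy (locus, zygosity, group, count) frame from a zygosity table."""
    import pandas as pd

    rows = []
    for locus, by_z in counts.items():
        for zyg, (a, b) in by_z.items():
            rows.append({"locus": locus, "zygosity": zyg,
                         "group": groups[0], "count": a})
            rows.append({"locus": locus, "zygosity": zyg,
                         "group": groups[1], "count": b})
    return pd.DataFrame(rows)


def genotype_counts_frame(counts: dict[str, tuple[int, int]],
                          groups: tuple[str, str]):
    """Tidy (category, group, count) frame from a combined-genotype table."""
    import pandas as pd

    rows = []
    for genotype, (a, b) in counts.items():
        rows.append({"category": genotype, "group": groups[0], "count": a})
        rows.append({"category": genotype, "group": groups[1], "count": b})
    return pd.DataFrame(rows)
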