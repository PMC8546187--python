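"""Bundled example data: published DE miRNA sets from a dairy-cattle study.

The example comes from a bovine mammary small-RNA study contrasting cows
with high versus low milk-protein percentage, sampled in lactation
(HP vs. LP) and in the non-lactating, dry period (HD vs. LD). The study
reported 28 DE miRNAs in lactation (11 up, 17 down in the low-protein
group), 52 in the dry period (22 up, 30 down), 14 miRNAs DE in both
contrasts, and a milk-protein-related regulatory network of DE miRNAs and
DE target genes. These lists make handy worked examples for the set
algebra and network census operations without any external download.

Identifier note: dashes are normalized to ASCII hyphens; everything else
is kept exactly as published.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "example_de_mirnas",
    "example_network_table",
]

# HP vs. LP (lactation): 11 up, 17 down in the low-protein group
HP_LP_UP = [
    "let-7a-3p", "let-7f", "miR-150", "miR-204", "miR-2478", "miR-320a",
    "miR-326", "miR-340", "miR-423-3p", "miR-423-5p", "miR-92b",
]
HP_LP_DOWN = [
    "miR-143", "miR-144", "miR-146a", "miR-146b", "miR-152", "miR-16a",
    "miR-185", "miR-24-3p", "miR-2904", "miR-34a", "miR-374a", "miR-379",
    "miR-382", "miR-411c-3p", "miR-425-3p", "miR-451", "miR-655",
]

# HD vs. LD (dry period): 22 up, 30 down in the low-protein group
HD_LD_UP = [
    "miR-1185", "miR-1296", "miR-132", "miR-147", "miR-149-5p", "miR-150",
    "miR-199a-5p", "miR-20b", "miR-2411-3p", "miR-2478", "miR-2887",
    "miR-2904", "miR-296-3p", "miR-326", "miR-331-3p", "miR-429", "miR-484",
    "miR-494", "miR-495", "miR-505", "miR-665", "miR-885",
]
HD_LD_DOWN = [
    "miR-1", "miR-100", "miR-10a", "miR-10b", "miR-1271", "miR-1388-5p",
    "miR-141", "miR-143", "miR-144", "miR-146a", "miR-146b", "miR-152",
    "miR-16a", "miR-185", "miR-192", "miR-195", "miR-196a", "miR-196b",
    "miR-24-3p", "miR-26a", "miR-26b", "miR-27b", "miR-30a-5p", "miR-374a",
    "miR-379", "miR-409a", "miR-486", "miR-6524", "miR-99a-5p", "miR-99b",
]

# Published milk-protein regulatory network: (contrast, miRNA, log2fc,
# p-value, adjusted p or None, target genes). One row per published entry;
# a miRNA may recur with different target lists.
_NETWORK_ROWS = [
    ("HP_vs_LP", "let-7a-3p", 0.90, 0.0351, 0.2489, ["BAMBI", "COL4A5", "DNAJC6"]),
    ("HP_vs_LP", "miR-150", 1.27, 0.0401, 0.2684, ["MYB"]),
    ("HP_vs_LP", "miR-144", -1.84, 0.0058, 0.0985, ["MYB"]),
    ("HP_vs_LP", "miR-16a", -0.94, 0.0422, 0.2706, ["MYB"]),
    ("HP_vs_LP", "miR-2478", 0.94, 0.0008, 0.0351, ["MYB"]),
    ("HP_vs_LP", "miR-146a", -1.35, 0.0002, 0.0094, ["ALOX15", "FABP3"]),
    ("HP_vs_LP", "miR-146b", -1.61, 4.15e-07, 0.0001, ["ALOX15", "FABP3"]),
    ("HP_vs_LP", "miR-2478", 0.94, 0.0008, 0.0351, ["ME3", "MYB"]),
    ("HP_vs_LP", "miR-2904", -0.84, 0.0203, 0.1910, ["DNAJC6"]),
    ("HP_vs_LP", "miR-374a", -0.94, 0.0053, 0.0985, ["MYB", "DUSP13"]),
    ("HD_vs_LD", "miR-1", -2.94, 0.0094, None, ["PSPH"]),
    ("HD_vs_LD", "miR-1296", 0.81, 0.0443, 0.1589, ["CCNB2"]),
    ("HD_vs_LD", "miR-141", -1.51, 0.0001, 0.0012, ["SMAD9", "ITGA8", "ATP6V0D2", "MAD2L1"]),
    ("HD_vs_LD", "miR-195", -1.00, 0.0056, 0.0329, ["CCNB2"]),
    ("HD_vs_LD", "miR-16a", -1.05, 0.0016, 0.0113, ["CCNB2"]),
    ("HD_vs_LD", "miR-1271", -1.36, 0.0017, 0.0123, ["COL2A1"]),
    ("HD_vs_LD", "miR-152", -1.28, 0.0005, 0.0048, ["COL2A1"]),
    ("HD_vs_LD", "miR-196b", -0.83, 0.0172, 0.0808, ["COL2A1"]),
    ("HD_vs_LD", "miR-196a", -1.38, 4.89e-06, 0.0001, ["COL2A1"]),
    ("HD_vs_LD", "miR-2887", 2.08, 0.0001, 0.0018, ["ANGPT4"]),
    ("HD_vs_LD", "miR-429", 1.05, 0.0002, 0.0025, ["SPP1"]),
    ("HD_vs_LD", "miR-505", 0.99, 0.0104, 0.0529, ["ACSBG1"]),
    ("HD_vs_LD", "miR-885", 2.14, 0.0355, None, ["NR1D1"]),
    ("HD_vs_LD", "miR-144", -3.43, 0.0007, 0.0060, ["ASF1B", "SPP1", "CDK1"]),
    ("HD_vs_LD", "miR-146a", -1.97, 0.0000, 0.0001, ["FABP3"]),
    ("HD_vs_LD", "miR-146b", -1.83, 3.37e-08, 4.04e-06, ["FABP4"]),
    ("HD_vs_LD", "miR-185", -1.79, 3.42e-06, 0.0001, ["SPP1", "FABP3"]),
    ("HD_vs_LD", "miR-2478", 1.56, 0.0001, 0.0014, ["KCNJ2"]),
    ("HD_vs_LD", "miR-2904", 1.31, 0.0470, 0.1612, ["PODN", "SFRP1"]),
]


def example_de_mirnas() -> dict[str, dict[str, list[str]]]:
    """Published DE miRNA name lists per contrast and direction."""
    return {
        "HP_vs_LP": {"up": list(HP_LP_UP), "down": list(HP_LP_DOWN)},
        "HD_vs_LD": {"up": list(HD_LD_UP), "down": list(HD_LD_DOWN)},
    }


def example_de_table(contrast: str) -> pd.DataFrame:
    """The published DE lists shaped as a DE table the filter accepts.

    Fold changes and p-values for list members are not all published, so
    up members get a nominal (log2fc, p) of (1.0, 0.01) and down members
    (-1.0, 0.01); the table is for set-level examples, not effect sizes.
    """
    sets = example_de_mirnas()[contrast]
    rows = [(m, 1.0, 0.01) for m in sets["up"]] + [
        (m, -1.0, 0.01) for m in sets["down"]
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "log2fc", "pvalue"])


def example_network_table() -> pd.DataFrame:
    """Published milk-protein network as a flat miRNA -> gene edge list.

    Columns: contrast, mirna_id, log2fc, pvalue, padj, gene_id — one row
    per (entry, target gene); duplicated entries are kept as published.
    """
    rows = []
    for contrast, mirna, lfc, p, padj, genes in _NETWORK_ROWS:
        for gene in genes:
            rows.append((contrast, mirna, lfc, p, padj, gene))
    return pd.DataFrame(
        rows, columns=["contrast", "mirna_id", "log2fc", "pvalue", "padj", "gene_id"]
    )
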