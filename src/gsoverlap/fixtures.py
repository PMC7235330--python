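"""Packaged gene lists used as small real-data fixtures.

Two published symbol lists ship with the package as one-symbol-per-line
text files: the 25 GWAS-derived schizophrenia genes matching
well-recognized brain ischemia-hypoxia response genes, and the 33
schizophrenia genes annotated for a role of the hypoxia-inducible
factors. They exercise the symbol-list reader on real human symbols; the
full external databases (GWAS list, LoF, SynGO, IHR/BH/HDB) are not
redistributable and are supplied by the user at run time.
"""

from __future__ import annotations

from importlib import resources

from .geneset_store import GeneSet, read_symbol_list

__all__ = ["table1_ihr_matched_genes", "table2_hif_annotated_genes"]


def _load(filename: str, name: str) -> GeneSet:
    path = resources.files("gsoverlap").joinpath("data", filename)
    with resources.as_file(path) as real_path:
        return read_symbol_list(real_path, name=name)


def table1_ihr_matched_genes() -> GeneSet:
    """25 schizophrenia GWAS genes matching brain ischemia-hypoxia response genes."""
    return _load("scz_gwas_ihr_matched.txt", "SCZ_GWAS_IHR_MATCHED")


def table2_hif_annotated_genes() -> GeneSet:
    """33 schizophrenia GWAS genes annotated for hypoxia-inducible factor roles."""
    return _load("scz_gwas_hif_annotated.txt", "SCZ_GWAS_HIF_ANNOTATED")
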