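"""th1regnet: regulatory-genomics analysis of cytokine-driven CD4+ T cells.

The package reimplements, as a tested library, a multiomic pipeline that
identifies transcriptional regulators of *Il10* in Th1/Tr1 cells: temporal
expression clustering, TF-target correlation screening, SVD attribution of
weak conditional-knockout effects, differential Tn5 footprinting, and
direct-target network construction from ATAC-seq, ChIP-seq and motif
evidence.  A synthetic-data module plants known signal at every stage.
"""

from importlib.resources import files as _files

__version__ = "0.1.0"


def cns_table_path() -> str:
    """Path to the bundled mm10 conserved non-coding sequence coordinate
    table for the Il10, Prdm1, Ifng and Maf loci."""
    return str(_files("th1regnet").joinpath("data/cns_mm10.tsv"))
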