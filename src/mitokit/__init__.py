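"""mitokit: comparative mitogenomics — annotation QC, signed circular
gene-order rearrangement analysis, and codon-usage bias statistics."""

from importlib import resources

import pandas as pd

from . import (  # noqa: F401
    codon_usage,
    composition_stats,
    genbank_io,
    gene_order,
    synthetic_data,
    vocab,
)

__version__ = "0.1.0"

INGROUP_GROUPS = ("Axiidea", "Gebiidea", "Caridea")
OUTGROUP_GROUP = "Dendrobranchiata"


def load_study_manifest() -> pd.DataFrame:
    """The bundled study manifest: 45 accessions with taxon, group, gene-order
    pattern, and ingroup/outgroup role."""
    with resources.files("mitokit.data").joinpath("study_manifest.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_study_tree() -> str:
    """Newick topology matching the bundled study manifest (leaves are
    record ids)."""
    return resources.files("mitokit.data").joinpath("study_tree.nwk").read_text().strip()
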