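"""divergene: candidate-gene discovery between divergently bred mouse lines.

A tested, reusable implementation of a two-line brain-region
transcriptome pipeline: two-colour microarray normalization (MA plane,
global median, intensity-dependent LOESS, sub-array balancing),
permutation maxT differential expression, cross-region candidate
selection, 2^-ddCt qPCR quantification, allelic variant annotation and
clustering, and nonparametric group statistics -- together with a
synthetic-data generator that emulates the study design with known
ground truth.
"""

from importlib import resources

__version__ = "0.1.0"

from . import candidates, detest, groupstats, qpcr, synth, twocolor, variants  # noqa: F401,E402


def ctsb_variant_table():
    """The bundled synthetic Ctsb HAB/LAB variant catalogue.

    A synthetic transcription: positions are invented, but every
    published summary of the locus holds by construction (76 SNPs,
    8 insertions, 9 deletions; 10 SNPs + 2 insertions in the promoter;
    8 exonic sites, all SNPs; dense clusters in the promoter, introns
    3-4 and the downstream enhancer region).
    """
    from .variants import read_variant_table
    with resources.as_file(
            resources.files("divergene.data") / "ctsb_variants_synthetic.tsv") as p:
        return read_variant_table(p)


def ctsb_gene_model():
    """The synthetic Ctsb gene model matching the bundled variant table."""
    from .variants import GeneModel
    with resources.as_file(
            resources.files("divergene.data") / "ctsb_model_synthetic.yaml") as p:
        return GeneModel.from_yaml(p)
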