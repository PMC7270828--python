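"""epipair: reference-free reconstruction of pre-bisulfite GBS fragments.

A toolkit for single-enzyme bisulfite GBS libraries in which genomic
fragments are inserted in both orientations between a barcoded adapter
and a hemimethylated common adapter.  Because bisulfite conversion maps
C to T (pyrimidine to pyrimidine), the purine/pyrimidine image of each
locus is conversion-invariant and the two strand images of a fragment can
be paired and decoded back into the original sequence with per-position
methylation calls.  The reconstructed fragments are stitched into a mock
genome usable as a mapping reference.
"""

from importlib.resources import files

__version__ = "0.1.0"


def default_barcode_table() -> dict[str, str]:
    """The packaged 8-sample barcode table."""
    from .preprocess import load_barcode_table

    return load_barcode_table(str(files("epipair") / "data" / "barcodes.tsv"))
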