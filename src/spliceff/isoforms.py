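"""SATB1 protein isoform constants.

The two murine SATB1 isoforms differ by a single extra exon: the short
isoform (UniProtKB Q60611) is 764 aa, the long isoform (UniProtKB E9PVB7)
795 aa.  The extra peptide encoded by the additional exon sits between the
CUT2 domain and the homeodomain.
"""

SATB1_SHORT_AA = 764  # UniProtKB Q60611
SATB1_LONG_AA = 795   # UniProtKB E9PVB7

__all__ = ["SATB1_SHORT_AA", "SATB1_LONG_AA", "extra_peptide_length"]


def extra_peptide_length(long_aa: int = SATB1_LONG_AA,
                         short_aa: int = SATB1_SHORT_AA) -> int:
    """Length (aa) of the peptide unique to the long isoform."""
    if long_aa <= short_aa:
        raise ValueError("long isoform must be longer than the short one")
    return long_aa - short_aa
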