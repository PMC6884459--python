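"""Deletion-allele arithmetic for PCR genotyping.

A jump-out deletion screen identifies null alleles by amplicon shortening:
primers straddling the excision site give a fixed-length product on the
wild-type template and a product shortened by the deleted span on a deletion
chromosome. This module does the bookkeeping — fraction of the coding region
removed and the expected mutant amplicon length.
"""

from __future__ import annotations

from .datamodel import DeletionSummary


def describe_deletion(
    codons_removed: int,
    codons_total: int,
    wt_amplicon_bp: int,
    deletion_bp: int,
) -> DeletionSummary:
    """Summarize a coding-region deletion.

    Parameters
    ----------
    codons_removed : codons of the coding sequence removed by the deletion.
    codons_total : total codons of the coding sequence.
    wt_amplicon_bp : genotyping-PCR product length on wild-type template.
    deletion_bp : length of the deleted span; must not exceed the wild-type
        amplicon.

    Returns
    -------
    DeletionSummary with ``coding_loss_pct`` (integer percent, rounded) and
    ``expected_mutant_amplicon_bp`` (wild-type amplicon minus deletion).
    """
    codons_removed = int(codons_removed)
    codons_total = int(codons_total)
    wt_amplicon_bp = int(wt_amplicon_bp)
    deletion_bp = int(deletion_bp)
    if deletion_bp > wt_amplicon_bp:
        raise ValueError(
            f"deletion ({deletion_bp} bp) exceeds the wild-type amplicon "
            f"({wt_amplicon_bp} bp)"
        )
    return DeletionSummary(
        codons_removed=codons_removed,
        codons_total=codons_total,
        coding_loss_pct=round(100 * codons_removed / codons_total),
        wt_amplicon_bp=wt_amplicon_bp,
        deletion_bp=deletion_bp,
        expected_mutant_amplicon_bp=wt_amplicon_bp - deletion_bp,
    )
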