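"""Paths to the small data files shipped with the package."""

from __future__ import annotations

from importlib import resources


def _path(name: str):
    return resources.files("forkasym").joinpath("data", name)


def poldelta_mutant_counts_path():
    """Observed strand-bias mispair counts for the polδ-L591M reporter strains."""
    return _path("poldelta_L591M_strand_bias_counts.tsv")


def poldelta_wt_counts_path():
    """Observed strand-bias mispair counts for the polδ+ control strains."""
    return _path("poldelta_wt_strand_bias_counts.tsv")


def invitro_prior_path():
    """Relative in-vitro error rates of the orthologous polδ L612M mutant."""
    return _path("invitro_prior_poldelta_L612M.tsv")


def reference_fasta_path():
    """Synthetic 1.6 kb reporter reference sequence (ura4:ura5 stand-in)."""
    return _path("synthetic_reporter_reference.fasta")
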