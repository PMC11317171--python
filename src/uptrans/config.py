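"""Tunable parameters for the upstream-translation pipeline.

Defaults follow the published operating points: tryptic peptides of 7-40
residues with up to two missed cleavages, a posterior-error-probability
ceiling of 2e-4, UTRs of at least 20 nt, and a clade-conservation species
fraction of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class DbConfig:
    """Search-database construction parameters."""

    min_orf_aa: int = 7          # shortest UTR 3-frame fragment kept (= min peptide length)
    cds_prefix_aa: int = 60      # CDS codons fused onto upstream extensions
    min_utr_nt: int = 20         # UTRs shorter than this are skipped
    decoy_mode: str = "segment"  # "segment" (per-tryptic-segment reversal) or "whole"


@dataclass
class FilterConfig:
    """PSM acceptance rules applied after search-engine rescoring."""

    pep_max: float = 0.0002      # inclusive posterior error probability ceiling
    min_len: int = 7
    max_len: int = 40
    max_missed_cleavages: int = 2
    il_equivalent: bool = True   # treat I and L as indistinguishable when mapping
    no_cleave_before_p: bool = True  # trypsin does not cut K/R-P bonds


@dataclass
class ConservationConfig:
    """Clade-binning rules."""

    min_clade_fraction: float = 0.5   # fraction of alignable species that must conserve frame
    require_start_conserved: bool = True


@dataclass
class PipelineConfig:
    db: DbConfig = field(default_factory=DbConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    conservation: ConservationConfig = field(default_factory=ConservationConfig)
    af_cutoff: float = 0.005     # rare/common allele-frequency split
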