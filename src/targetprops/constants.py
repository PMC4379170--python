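"""Pinned physico-chemical constants and canonical feature schema.

Everything that downstream modules treat as fixed vocabulary lives here:
the Kyte-Doolittle hydropathy index, the pKa table used for isoelectric
point calculation (EMBOSS pepstats values), amino-acid category
memberships, the UniProt keyword -> protein-family map and the canonical
order of the assembled feature columns.
"""

from __future__ import annotations

# The twenty standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# IUPAC ambiguity codes resolved as half-counts to each member.
AMBIGUOUS_AA = {
    "B": ("D", "N"),
    "J": ("I", "L"),
    "Z": ("E", "Q"),
}

# X: unknown residue; contributes to sequence length but to no count.
UNKNOWN_AA = "X"

VALID_AA = set(STANDARD_AA) | set(AMBIGUOUS_AA) | {UNKNOWN_AA}

# Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# pKa values as used by EMBOSS pepstats (version-pinned; see docs/methods.md).
PKA = {
    "N_TERM": 8.6,
    "C_TERM": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
# Residues carrying positive charge below their pKa / negative above it.
BASIC_RESIDUES = ("H", "K", "R")
ACIDIC_RESIDUES = ("C", "D", "E", "Y")

# Amino-acid category memberships.
AA_CATEGORIES = {
    "tiny": "ACGST",
    "small": "ACDGNPSTV",
    "aliphatic": "ILV",
    "aromatic": "FHWY",
    "non_polar": "ACFGILMPVWY",
    "charged": "DEHKR",
    "positively_charged": "HKR",
    "negatively_charged": "DE",
}

# UniProt keyword id -> protein family.
KEYWORD_FAMILIES = {
    "KW-0297": "gpcr",
    # Ion channels.
    "KW-1071": "ion_channel",
    "KW-0851": "ion_channel",
    "KW-0107": "ion_channel",
    "KW-0869": "ion_channel",
    "KW-0407": "ion_channel",
    "KW-0631": "ion_channel",
    "KW-0894": "ion_channel",
    # Kinases.
    "KW-0418": "kinase",
    "KW-0723": "kinase",
    "KW-0829": "kinase",
    # Proteases.
    "KW-0031": "protease",
    "KW-0064": "protease",
    "KW-0121": "protease",
    "KW-0224": "protease",
    "KW-0482": "protease",
    "KW-0645": "protease",
    "KW-0720": "protease",
    "KW-0788": "protease",
    "KW-0888": "protease",
}

KINASE_TYPES = ("ser_thr", "tyr", "atypical", "unknown")
PROTEASE_TYPES = ("aspartic", "cysteine", "metallo", "serine", "threonine",
                  "unknown")

N_BODY_SITES = 45
N_DEV_STAGES = 7

# ---------------------------------------------------------------------------
# Canonical feature-column order: alphabetical within each feature group.
# ---------------------------------------------------------------------------

AA_FREQ_FEATURES = tuple(f"freq_{aa}" for aa in STANDARD_AA)

CATEGORY_FEATURES = tuple(
    f"frac_{name}" for name in sorted(AA_CATEGORIES)
)

SIMPLE_FEATURES = (
    "hydrophobicity",
    "isoelectric_point",
    "low_complexity_regions",
    "pest_motifs",
    "sequence_length",
    "signal_peptide",
)

PTM_FEATURES = (
    "n_glyc_sites",
    "o_glyc_sites",
    "phospho_ser",
    "phospho_thr",
    "phospho_total",
    "phospho_tyr",
)

SECONDARY_FEATURES = (
    "frac_beta_strand",
    "frac_buried_helix",
    "frac_exposed_helix",
    "tm_helices",
)

VARIANT_FEATURES = (
    "var_3utr",
    "var_5utr",
    "var_nonsyn",
    "var_syn",
)

RELATIONAL_FEATURES = (
    "alt_transcripts",
    "binary_ppis",
    "paralogues",
)

DEV_STAGE_FEATURES = tuple(
    f"dev_stage_{i + 1}" for i in range(N_DEV_STAGES)
)
BODY_SITE_FEATURES = tuple(
    f"body_site_{i + 1}" for i in range(N_BODY_SITES)
)
EXPRESSION_FEATURES = DEV_STAGE_FEATURES + BODY_SITE_FEATURES + (
    "body_sites_expressed",
)

FEATURE_NAMES = (
    AA_FREQ_FEATURES
    + CATEGORY_FEATURES
    + SIMPLE_FEATURES
    + PTM_FEATURES
    + SECONDARY_FEATURES
    + VARIANT_FEATURES
    + RELATIONAL_FEATURES
    + EXPRESSION_FEATURES
)

N_FEATURES = len(FEATURE_NAMES)

# Features never submitted to the per-feature significance test: the raw
# expression levels (mostly zero) and the tiny/small category fractions
# (near-identical class distributions). The derived expression-breadth
# count is tested.
DEFAULT_UNTESTED_FEATURES = frozenset(
    DEV_STAGE_FEATURES + BODY_SITE_FEATURES + ("frac_tiny", "frac_small")
)
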