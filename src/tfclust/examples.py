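"""Reference hub-centered presence tables from human cardiomyogenesis.

Four TFBS clusters — centered on the AP-1, HMGIY, SMAD, and NFAT binding
sites — were reported across five stages of in vitro human heart-muscle
development (days 0-3, 3-8, 8-13, 13-29, 29-60).  Their published pair x
stage presence rows are encoded here as worked examples for the
stage-analysis operations, together with the headline per-stage DEG, pair,
and cluster counts used by the hourglass profile.
"""
from __future__ import annotations

from .stages import StagePresenceTable

STAGE_NAMES = (
    "mesoderm_induction",
    "early_specification",
    "late_specification",
    "early_maturation",
    "late_maturation",
)

_T, _F = True, False

AP1_CLUSTER_ROWS: dict[str, tuple[bool, ...]] = {
    "V$OCT_C": (_T, _T, _F, _F, _T),
    "V$GATA_Q6": (_T, _T, _F, _T, _T),
    "V$HNF4_Q6": (_F, _T, _F, _F, _F),
}

HMGIY_CLUSTER_ROWS: dict[str, tuple[bool, ...]] = {
    "V$OCT_Q6": (_T, _T, _T, _T, _T),
    "V$NFKAPPAB_01": (_T, _T, _F, _T, _T),
    "V$NFKB_Q6_01": (_T, _T, _T, _T, _T),
    "V$NFKB_Q6": (_T, _F, _F, _F, _F),
    "V$ATF3_Q6": (_T, _T, _F, _F, _T),
}

SMAD_CLUSTER_ROWS: dict[str, tuple[bool, ...]] = {
    "V$FOX_Q2": (_T, _T, _T, _T, _T),
    "V$AP1FJ_Q2": (_T, _T, _F, _T, _T),
    "V$LEF1TCF1_Q4": (_F, _T, _T, _F, _F),
}

NFAT_CLUSTER_ROWS: dict[str, tuple[bool, ...]] = {
    "V$PEBP_Q6": (_T, _F, _F, _F, _F),
    "V$AP1_C": (_T, _T, _T, _T, _T),
    "V$CEBPB_01": (_T, _T, _F, _T, _T),
    "V$CREBP1CJUN_01": (_T, _T, _T, _T, _T),
    "V$MAF_Q6_01": (_T, _T, _T, _T, _T),
    "V$ETS1_B": (_T, _F, _F, _F, _F),
}

CLUSTER_TABLES: dict[str, tuple[str, dict[str, tuple[bool, ...]]]] = {
    "AP1": ("V$AP1_01", AP1_CLUSTER_ROWS),
    "HMGIY": ("V$HMGIY_Q6", HMGIY_CLUSTER_ROWS),
    "SMAD": ("V$SMAD_Q6_01", SMAD_CLUSTER_ROWS),
    "NFAT": ("V$NFAT_Q6", NFAT_CLUSTER_ROWS),
}

# headline per-stage counts reported for the study's time course
PAIR_COUNTS_PER_STAGE = (63, 82, 24, 52, 76)
DEG_COUNTS_PER_STAGE = (429, 1233, 36, 205, 964)
CLUSTER_COUNTS_PER_STAGE = (19, 25, 11, 21, 24)

FPKM_THRESHOLD = 10.0


def presence_table(name: str) -> StagePresenceTable:
    """Build the reference StagePresenceTable for one of AP1/HMGIY/SMAD/NFAT."""
    hub, rows = CLUSTER_TABLES[name]
    return StagePresenceTable(hub=hub, rows=dict(rows), stage_names=STAGE_NAMES)
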