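"""Published blackcap (Sylvia atricapilla) TE-annotation summary numbers.

These are the printed per-class copy counts and total lengths of the raw
RepeatMasker annotation and of the final curated (defragmented, 80-80-80
filtered) TE annotation of the blackcap reference genome, plus the
recent-insertion accounting derived from the K <= 7 age split.  They serve
as reference inputs for arithmetic cross-checks of the summary machinery:
shares of total TE bp and copies per class, the recent/ancient bookkeeping
and the genome fraction are all recomputable from these rows.
"""

from __future__ import annotations

# class -> (copies, total_bp) of the raw RepeatMasker annotation
BLACKCAP_RAW = {
    "SINE": (4269, 463_447),
    "LINE": (127_084, 35_233_072),
    "LTR": (82_330, 43_924_839),
    "DNA": (4279, 1_160_803),
    "Unclassified": (487, 204_826),
}

# class -> (copies, total_bp) of the final curated TE annotation
BLACKCAP_FINAL = {
    "SINE": (1466, 182_635),
    "LINE": (61_906, 19_307_025),
    "LTR": (45_188, 33_395_659),
    "DNA": (965, 483_169),
}

# printed genome fraction of the raw annotation (%), anchoring assembly size
BLACKCAP_RAW_PCT = 7.68

# recent-insertion accounting (divergence K <= 7, inclusive)
BLACKCAP_RECENT_BP = 10_612_698
BLACKCAP_RECENT_COPIES = 9404
# recent LTR copies as a fraction of all LTR copies (printed percent)
BLACKCAP_RECENT_LTR_OF_LTR_PCT = 19.4


def raw_total_bp() -> int:
    return sum(bp for _, bp in BLACKCAP_RAW.values())


def final_total_bp() -> int:
    return sum(bp for _, bp in BLACKCAP_FINAL.values())


def final_total_copies() -> int:
    return sum(n for n, _ in BLACKCAP_FINAL.values())


def assembly_length() -> float:
    """Assembly length implied by the raw totals and their printed percent."""
    return raw_total_bp() / (BLACKCAP_RAW_PCT / 100.0)
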