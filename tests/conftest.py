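"""Shared fixtures: simulated families and the reference topology used in
monophyly tests."""

from __future__ import annotations

import pytest

from rptp.simulate import default_config, simulate_family

#: Backbone topology of the family as reported for metazoan R3 RPTPs:
#: five vertebrate clades (PTPRQ, PTPRB, PTPRO, PTPRJ, PTPRH), PTPRJ+PTPRH
#: sisters, tunicate sequences splitting between the PTPRQ-side and
#: PTPRB-side clusters, monophyletic protostomes, sponge early-diverged.
REFERENCE_TOPOLOGY = (
    "(Sponge,"
    "(((Ciona_2,Ciona,Acorn_worm,(Sea_urchin_3,Sea_urchin_4)),"
    "(Hs_PTPRQ,Mm_PTPRQ,Gg_PTPRQ,Xt_PTPRQ,Dr_PTPRQ)),"
    "((Annelid,(Fly_PTP10D,Fly_PTP4e),(Nematode_1,Nematode_2)),"
    "((Ciona_1,Ciona_3,(Hs_PTPRB,Mm_PTPRB,Dr_PTPRB)),"
    "((Hs_PTPRO,Mm_PTPRO),"
    "((Hs_PTPRJ,Mm_PTPRJ),(Hs_PTPRH,Mm_PTPRH)))))));"
)

VERTEBRATE_GROUPS = {
    "PTPRQ": {"Hs_PTPRQ", "Mm_PTPRQ", "Gg_PTPRQ", "Xt_PTPRQ", "Dr_PTPRQ"},
    "PTPRB": {"Hs_PTPRB", "Mm_PTPRB", "Dr_PTPRB"},
    "PTPRO": {"Hs_PTPRO", "Mm_PTPRO"},
    "PTPRJ": {"Hs_PTPRJ", "Mm_PTPRJ"},
    "PTPRH": {"Hs_PTPRH", "Mm_PTPRH"},
}

PROTOSTOMES = {"Annelid", "Fly_PTP10D", "Fly_PTP4e",
               "Nematode_1", "Nematode_2"}


@pytest.fixture(scope="session")
def family():
    """One simulated family under the default study conditions."""
    return simulate_family(default_config(seed=42))


@pytest.fixture(scope="session")
def family_zero_rate():
    """Family with zero branch lengths: every leaf equals its planted plan."""
    cfg = default_config(seed=7)
    import re

    tree = re.sub(r":\d*\.?\d+", ":0.0", cfg.tree)
    cfg.tree = tree
    return simulate_family(cfg)
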