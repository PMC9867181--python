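import pytest

from sscoi.primers import SPONGY_MOTH_FWD, SPONGY_MOTH_REV
from sscoi.seqio import LabeledAlignment, Role, SequenceRecord
from sscoi.synthetic_panel import PanelSpec, PlantedSites, simulate_panel

#: planted product size used across fixtures: forward start to reverse end
PLANTED_PRODUCT = 543
PLANT_FWD_POS = 60
PLANT_REV_POS = PLANT_FWD_POS + PLANTED_PRODUCT - len(SPONGY_MOTH_REV)


def make_alignment(rows):
    """rows: iterable of (id, species, role, residues)."""
    return LabeledAlignment(
        records=tuple(
            SequenceRecord(id=i, species=s, role=Role.parse(r), residues=seq)
            for i, s, r, seq in rows
        )
    )


@pytest.fixture(scope="session")
def planted_panel():
    """Synthetic panel with the published diagnostic primer sites planted
    into every target sequence (forward at 60, product 543 bp)."""
    spec = PanelSpec(
        seed=42,
        planted_sites=PlantedSites(
            SPONGY_MOTH_FWD, SPONGY_MOTH_REV, PLANT_FWD_POS, PLANT_REV_POS
        ),
    )
    return simulate_panel(spec)


@pytest.fixture(scope="session")
def plain_panel():
    return simulate_panel(PanelSpec(seed=7))
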