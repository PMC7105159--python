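import numpy as np
import pytest

import plasmacna as pc


@pytest.fixture(scope="session")
def layout():
    """Desk-scale study layout: 22 autosomes, 1 Mb bins (~2900 bins)."""
    return pc.default_layout()


@pytest.fixture(scope="session")
def toy():
    """Two 50 Mb chromosomes at 1 Mb bins: 100 bins."""
    return pc.toy_layout(2, 50_000_000)


@pytest.fixture(scope="session")
def gc_track(layout):
    return pc.synthetic.simulate_gc_track(layout, seed=11)


@pytest.fixture(scope="session")
def donor_profiles(layout, gc_track):
    """25 healthy-donor count profiles at the generator defaults."""
    return [
        pc.synthetic.simulate_donor_counts(
            layout, gc_track, seed=100 + d, sample_id=f"donor-{d:02d}"
        )
        for d in range(25)
    ]


@pytest.fixture(scope="session")
def panel(donor_profiles):
    return pc.build_panel(donor_profiles)
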