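import numpy as np
import pandas as pd
import pytest

from quadgait import io as qio
from quadgait import synth


def make_series(contacts, lifts, limb="RH", **meta):
    defaults = dict(animal_id="A1", timepoint="BL", pass_id="P1")
    defaults.update(meta)
    return qio.LimbEventSeries(limb=qio.Limb(limb), contacts=np.asarray(contacts),
                               lifts=np.asarray(lifts), **defaults)


@pytest.fixture
def simple_series():
    return make_series([0.0, 0.5, 1.0], [0.3, 0.8])


@pytest.fixture
def small_control_scenario():
    """A compact control scenario for fast end-to-end tests."""
    from dataclasses import replace

    base = synth.get_preset("control_overground", seed=11)
    return replace(base, n_animals=3, passes_per_animal=4)


@pytest.fixture
def small_silenced_scenario():
    from dataclasses import replace

    base = synth.get_preset("lapn_silenced", seed=12)
    return replace(base, n_animals=3, passes_per_animal=4)


def write_dataset(tmp_path, scenarios):
    """Write pooled events.csv / markers.csv for one or more scenarios."""
    events, markers = [], {}
    for sc in scenarios:
        ev, mk = synth.simulate_scenario(sc)
        events.extend(ev)
        markers.update(mk)
    qio.write_event_table(events, tmp_path / "events.csv")
    rows = []
    for (animal, pass_id), tracks in sorted(markers.items()):
        for name, track in sorted(tracks.items()):
            for frame, (x, y) in enumerate(track.xy):
                rows.append({"animal": animal, "pass": pass_id, "frame": frame,
                             "marker": name, "x_cm": x, "y_cm": y})
    pd.DataFrame(rows).to_csv(tmp_path / "markers.csv", index=False)
    return tmp_path / "events.csv", tmp_path / "markers.csv"
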