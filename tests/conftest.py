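import numpy as np
import pytest

from oncomotion import AcquisitionMeta, Trajectory


@pytest.fixture
def meta():
    return AcquisitionMeta(pixel_size_um=0.415, frame_interval_min=10.0)


@pytest.fixture
def spots_csv(tmp_path):
    """Handwritten 25-row Spots table: 3 tracks of lengths 12, 9, 4 (pixels)."""
    lines = ["TRACK_ID,FRAME,POSITION_X,POSITION_Y"]
    rng = np.random.default_rng(7)
    for tid, length in ((0, 12), (1, 9), (2, 4)):
        x0, y0 = rng.uniform(100, 900, 2)
        for f in range(length):
            lines.append(f"{tid},{f},{x0 + 3.0 * f:.4f},{y0 + 1.5 * f:.4f}")
    p = tmp_path / "spots.csv"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def zones_json(tmp_path):
    p = tmp_path / "coordinates.json"
    p.write_text(
        '{"unit": "um", "zones": ['
        '{"name": "A", "rect": [100, 50, 300, 250]},'
        '{"name": "B", "polygon": [[300, 50], [500, 50], [500, 250], [300, 250]]}'
        "]}"
    )
    return p


def make_track(track_id, xs, ys, frames=None, interval=10.0):
    xs = np.asarray(xs, float)
    if frames is None:
        frames = np.arange(len(xs))
    return Trajectory(track_id, np.asarray(frames), xs, np.asarray(ys, float), interval)
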