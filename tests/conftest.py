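import numpy as np
import pytest

from gistmem.geometry import Layout, Point, Screen
from gistmem.study_data import RetrievalRecord
from gistmem.synthetic import calibrate_layout, load_preset

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def exp1_layout() -> Layout:
    """Six-item layout calibrated to the published chance distances 348/267/270 px."""
    targets, _, n_items, screen = load_preset("exp1", FIXTURE_SEED)
    return calibrate_layout(targets, n_items, screen, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def exp2_layout() -> Layout:
    """Eight-item outlier layout calibrated to 386/262/223 px with a 573-px outlier."""
    targets, _, n_items, screen = load_preset("exp2", FIXTURE_SEED)
    return calibrate_layout(targets, n_items, screen, seed=FIXTURE_SEED)


@pytest.fixture
def toy_layout() -> Layout:
    """Small hand-built layout for arithmetic-oracle tests."""
    return Layout(
        screen=Screen(1000, 800),
        labels=("a", "b", "c"),
        points=(Point(300, 300), Point(700, 300), Point(500, 600)),
    )


def make_record(layout: Layout, retrieved, reported_center, pid="p001", session="S1",
                group="24h") -> RetrievalRecord:
    if isinstance(retrieved, dict):
        rmap = {lab: Point(*retrieved[lab]) for lab in layout.labels}
    else:
        rmap = {lab: Point(*xy) for lab, xy in zip(layout.labels, retrieved)}
    return RetrievalRecord(
        participant_id=pid,
        session=session,
        delay_group=group,
        retrieved=rmap,
        reported_center=Point(*reported_center),
    )


@pytest.fixture
def perfect_record(toy_layout):
    """Retrievals exactly on the encoded points, center reported at the true center."""
    tc = toy_layout.true_center
    return make_record(
        toy_layout, [(p.x, p.y) for p in toy_layout.points], (tc.x, tc.y)
    )


def random_points(rng: np.random.Generator, n: int, screen: Screen) -> list[Point]:
    xy = rng.uniform([0, 0], [screen.width, screen.height], size=(n, 2))
    return [Point(float(x), float(y)) for x, y in xy]
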