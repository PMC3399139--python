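import numpy as np
import pytest

from islandclock.calibration import (
    CalibrationEntry,
    CalibrationPrior,
    CalibrationTable,
)
from islandclock.trees import RootedTimeTree

#: Island ages (Ma) and the soft/punctual parameters conventionally printed
#: for the three re-analysed Hawaiian studies: (mean, sd, lower, upper).
ISLAND_CALIBRATION_ROWS = [
    (2.6, 1.1, 2.59, 2.61),   # Oahu (spider study)
    (3.7, 1.6, 3.69, 3.71),   # Oahu (damselfly study)
    (1.6, 0.7, 1.59, 1.61),   # Maui Nui
    (0.5, 0.2, 0.49, 0.51),   # Hawaii
    (5.2, 2.2, 5.19, 5.21),   # Niihau
    (4.7, 2.0, 4.69, 4.71),   # Kauai
    (3.0, 1.3, 2.99, 3.01),   # Oahu (lobeliad study)
    (0.6, 0.3, 0.59, 0.61),   # Hawaii (lobeliad study)
]


@pytest.fixture
def quartet_tree() -> RootedTimeTree:
    return RootedTimeTree.from_newick("((a,b),(c,d));")


@pytest.fixture
def quartet_tree_with_ages(quartet_tree) -> RootedTimeTree:
    ages = np.zeros(quartet_tree.n_nodes)
    for node in quartet_tree.internal_nodes:
        clade = quartet_tree.clade_labels(node)
        ages[node] = {("a", "b"): 1.0, ("c", "d"): 1.5, ("a", "b", "c", "d"): 2.6}[clade]
    return quartet_tree.with_ages(ages)


@pytest.fixture
def root_normal_calibration(quartet_tree) -> CalibrationTable:
    """Single soft calibration on the quartet root, spider-study style."""
    return CalibrationTable((
        CalibrationEntry("a", "d", "Oahu", 2.6,
                         CalibrationPrior("normal", mean=2.6, sd=1.1)),
    ))
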