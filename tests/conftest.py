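import numpy as np
import pytest

from colposeg import BinaryMask
from colposeg.fixtures import SceneSpec, StructureSpec, generate_scenes


def rect_mask(row, col, h, w, frame=(40, 40)):
    arr = np.zeros(frame, dtype=bool)
    arr[row : row + h, col : col + w] = True
    return BinaryMask(arr)


@pytest.fixture
def ring_mask():
    """40x40 outer square with centered 10x10 hole: 1500 foreground px."""
    arr = np.zeros((100, 100), dtype=bool)
    arr[20:60, 20:60] = True
    arr[35:45, 35:45] = False
    return BinaryMask(arr)


@pytest.fixture
def scene_set():
    """Six varied scenes: cervix + epithelium ring + lesions, two patients."""
    specs = [
        SceneSpec(
            seed=100 + i,
            width_px=120,
            height_px=100,
            structures=(
                StructureSpec("ellipse-cervix"),
                StructureSpec(
                    "ring-epithelium",
                    attributes={"epithelium type": "metaplastic" if i % 2 else "original"},
                ),
                StructureSpec("multi-blob-lesion"),
            ),
            tags=("High quality image", "Stage 2—after application of acetic acid"),
            patient_id=f"P{i // 3}",
        )
        for i in range(6)
    ]
    _, aset = generate_scenes(specs)
    return aset
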