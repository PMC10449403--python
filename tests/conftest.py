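import numpy as np
import pytest

from scenebound import EmbeddingTable, SceneImage


@pytest.fixture(scope="session")
def basis_embeddings() -> EmbeddingTable:
    """Orthonormal basis vectors: every distinct word pair has cosine distance 1."""
    words = ["quick", "brown", "fox", "jumps", "over", "lazy", "dog", "cat"]
    eye = np.eye(len(words))
    return EmbeddingTable({w: eye[i] for i, w in enumerate(words)})


@pytest.fixture(scope="session")
def uniform_gray() -> SceneImage:
    return SceneImage("gray", np.full((350, 350, 3), 128, dtype=np.uint8))


@pytest.fixture(scope="session")
def step_image() -> SceneImage:
    """Left half black, right half white: one vertical luminance contour."""
    px = np.zeros((350, 350, 3), dtype=np.uint8)
    px[:, 175:] = 255
    return SceneImage("step", px)


def checkerboard(cell: int, size: int = 352) -> SceneImage:
    tile = np.indices((size, size)).sum(axis=0) // cell % 2
    px = (tile * 255).astype(np.uint8)[..., None].repeat(3, axis=2)
    return SceneImage(f"checker{cell}", px)
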