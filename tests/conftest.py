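"""Shared fixtures: a small synthetic gallery enrolled once per session."""

from __future__ import annotations

import pytest

import finprint as fp


def enroll_render(render, side: str = "right") -> fp.FinModel:
    """Enroll one synthetic render through the real pipeline."""
    mask = fp.extract_fin_mask(render.image)
    features = fp.detect_features(render.image, mask)
    return fp.FinModel(
        dolphin_name=render.name,
        side=side,
        image=render.image,
        features=features,
        sharpness=fp.sharpness(render.image, mask).value,
    )


@pytest.fixture(scope="session")
def small_sim() -> fp.GallerySim:
    """Six identities, two perturbed queries each (rotation <= 15 deg)."""
    return fp.generate_gallery(6, seed=11, n_queries=2, rotation_max_deg=15.0)


@pytest.fixture(scope="session")
def small_models(small_sim) -> list[fp.FinModel]:
    return [enroll_render(r) for r in small_sim.models]
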