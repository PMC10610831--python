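import pytest

from shredkit import lwc, synthgen as sg


@pytest.fixture(scope="session")
def calibration():
    return lwc.calibrate(90.0, 9.0)  # 10 px/mm


@pytest.fixture(scope="session")
def small_scene():
    """One ribbon per class, shadowed, with calibration block, 640 px canvas."""
    return sg.generate_scene(
        n_per_class={c: 1 for c in "YGPZ"},
        shadow_strength=0.3,
        seed=42,
        canvas=(640, 640),
        ppmm=10.0,
    )


@pytest.fixture(scope="session")
def shadow_free_scene():
    return sg.generate_scene(
        n_per_class={c: 1 for c in "YGPZ"},
        shadow_strength=0.0,
        seed=43,
        canvas=(640, 640),
        ppmm=10.0,
    )


def render_ribbon(length_mm, width_mm, curvature, rotation_deg, ppmm=10.0, canvas=500, label="Y"):
    spec = sg.RibbonSpec(
        class_label=label,
        length_mm=length_mm,
        width_mm=width_mm,
        curvature=curvature,
        center=(canvas / 2, canvas / 2),
        rotation_deg=rotation_deg,
        ppmm=ppmm,
    )
    mask, tl, tw = sg.generate_ribbon(spec, (canvas, canvas))
    return mask, tl, tw
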