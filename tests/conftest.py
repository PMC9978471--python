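import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dense_frame():
    """One dense static speckle frame (128x128, >=1e4 px) for statistics tests."""
    from ciliaspeckle.speckle_sim import ScattererField, SimConfig, render_speckle_frame

    cfg = SimConfig.from_pixels((128, 128), n_frames=2, seed=7)
    # >= 10 scatterers per speckle grain keeps the field Gaussian
    field = ScattererField.random(cfg.field_extent, 100.0, np.random.default_rng(7))
    return render_speckle_frame(field, cfg)


@pytest.fixture(scope="session")
def beating_velocity_run():
    """Shared end-to-end run: 5 Hz beating patch -> velocity stack -> waveform.

    Session-scoped because rendering 6000 frames dominates the suite runtime.
    """
    from ciliaspeckle.speckle_sim import MotionProgram, ScattererField, SimConfig, simulate_stack
    from ciliaspeckle.velocimetry import velocity_map_stack
    from ciliaspeckle.beat import roi_waveform

    cfg = SimConfig.from_pixels((24, 24), n_frames=6000, seed=11)
    field = ScattererField.random(cfg.field_extent, 100.0, np.random.default_rng(11))
    motion = MotionProgram.beating(5.0, 250.0, 150.0, 0.4)
    stack, trace = simulate_stack(field, motion, cfg)
    vstack = velocity_map_stack(stack)
    waveform = roi_waveform(vstack)
    return {
        "stack": stack,
        "trace": trace,
        "vstack": vstack,
        "waveform": waveform,
        "motion": motion,
        "config": cfg,
    }
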