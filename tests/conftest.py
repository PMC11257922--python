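import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _config_factory(name):
    from ripedetr.model import ModelConfig
    factories = {
        "baseline": ModelConfig.baseline,
        "pconv": lambda: ModelConfig.from_switches(pconv_block=True),
        "dat": lambda: ModelConfig.from_switches(aifi_dat=True),
        "slimneck": lambda: ModelConfig.from_switches(neck_mode="slimneck"),
        "ssff": lambda: ModelConfig.from_switches(neck_mode="ssff"),
        "slimneck_ssff": lambda: ModelConfig.from_switches(slimneck_ssff=True),
        "full": ModelConfig.full,
        "pconv1": lambda: ModelConfig.from_switches(pconv_stages=1),
        "pconv2": lambda: ModelConfig.from_switches(pconv_stages=2),
        "pconv4": lambda: ModelConfig.from_switches(pconv_stages=4),
    }
    return factories[name]()


@pytest.fixture(scope="session")
def profiles():
    """Lazy, session-cached architecture profiles at 640x640."""
    from ripedetr.profiler import profile_config
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = profile_config(_config_factory(name), 640)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def smoke_run(tmp_path_factory):
    """One 300-step smoke training run shared by the pipeline tests."""
    from ripedetr.config import RunConfig
    from ripedetr.train import run_training
    out = tmp_path_factory.mktemp("smoke")
    cfg = RunConfig(preset="smoke").apply_preset()
    cfg.train.seed = 7
    summary = run_training(cfg, out, verbose=False)
    return {"summary": summary, "out": out, "cfg": cfg}
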