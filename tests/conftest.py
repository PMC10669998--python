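import numpy as np
import pytest

from octattn.network import NetworkConfig, StageConfig, build_network


@pytest.fixture(scope="session")
def surrogate_run(tmp_path_factory):
    """The scaled-down headline experiment, run once per session.

    Trains the full default architecture for 10 epochs on the seeded
    separable synthetic dataset (60 train + 20 test per class, 40% RNFL
    thinning, speckle sd 0.05) and returns (TrainResult, MetricReport,
    output directory).  Several minutes of CPU; shared by the acceptance
    checks and the heatmap-localization test.
    """
    from octattn.io import run_experiment, surrogate_config

    out = tmp_path_factory.mktemp("surrogate")
    cfg = surrogate_config(seed=1, output_dir=str(out))
    result, report = run_experiment(cfg)
    return result, report, out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """A miniature but structurally complete architecture (fast, float64-able)."""
    return NetworkConfig(
        input_side=16,
        input_channels=2,
        stem_filters=4,
        stem_kernel=2,
        stem_stride=2,
        stages=(StageConfig(4, repeats=1),
                StageConfig(8, repeats=1, followed_by_downsample=False)),
        num_classes=2,
    )


@pytest.fixture
def tiny_net(tiny_config):
    return build_network(tiny_config, seed=7, dtype=np.float64)


def finite_difference_gradcheck(loss_fn, arrays_and_grads, rng, n_probes=3,
                                eps=1e-6, rtol=1e-4):
    """Compare analytic gradients against central differences at random entries.

    ``arrays_and_grads`` is an iterable of (parameter array, analytic grad)
    pairs; ``loss_fn()`` recomputes the scalar loss from current parameters.
    """
    for arr, grad in arrays_and_grads:
        for _ in range(n_probes):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            old = arr[idx]
            arr[idx] = old + eps
            lp = loss_fn()
            arr[idx] = old - eps
            lm = loss_fn()
            arr[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = grad[idx]
            denom = max(1e-8, abs(num), abs(ana))
            assert abs(num - ana) / denom < rtol, (
                f"gradient mismatch at {idx}: numeric {num}, analytic {ana}"
            )
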