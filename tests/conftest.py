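import numpy as np
import pytest

from eegaug.core import DatasetBundle, EEGSegment, StimulusTarget


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def segment(rng):
    """A small random 8-channel, 120-sample epoch."""
    return EEGSegment(rng.standard_normal((8, 120)), fs=64.0, subject_id="s01")


@pytest.fixture
def recon_bundle(rng):
    """Ten paired (EEG, spectrogram) segments with arbitrary content."""
    segments = [EEGSegment(rng.standard_normal((4, 40)), fs=64.0) for _ in range(10)]
    targets = [StimulusTarget(spec=rng.standard_normal((3, 40))) for _ in range(10)]
    return DatasetBundle(segments, targets, task="reconstruction")


def finite_difference_grad(f, tensor, eps=1e-6):
    """Central-difference gradient of scalar-valued f wrt one tensor's data."""
    num = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = tensor.data[i]
        tensor.data[i] = orig + eps
        fp = float(f().data)
        tensor.data[i] = orig - eps
        fm = float(f().data)
        tensor.data[i] = orig
        num[i] = (fp - fm) / (2 * eps)
    return num


def assert_grad_matches(f, tensors, rtol=1e-4, eps=1e-6):
    """Autodiff gradients of scalar f agree with finite differences."""
    for t in tensors:
        t.grad = None
    f().backward()
    for t in tensors:
        num = finite_difference_grad(f, t, eps=eps)
        got = t.grad if t.grad is not None else np.zeros_like(t.data)
        scale = np.abs(num) + 1e-8
        np.testing.assert_array_less(np.abs(got - num) / scale, rtol)
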