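import numpy as np
import pytest

from laryvid.ssim import ImageFrame, SSIMParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Uniform 5x5 window: cheap and easy to brute-force."""
    return SSIMParams(window_size=5, window_kind="uniform")


@pytest.fixture
def manifest_for_split():
    """Factory for in-memory manifests with configurable class/patient mix."""
    import pandas as pd

    from laryvid.video_io import DatasetManifest

    def build(counts, frames_per=1):
        rows = []
        for label, n_patients in counts.items():
            for p in range(n_patients):
                for f in range(frames_per):
                    rows.append(
                        dict(
                            file_path=f"{label}_{p}_{f}.png",
                            video_id=f"{label}_{p}",
                            patient_id=f"{label}_{p}",
                            class_label=label,
                            frame_index=f,
                            split="none",
                        )
                    )
        return DatasetManifest(pd.DataFrame(rows))

    return build


@pytest.fixture
def random_frame_pair(rng):
    shape = (24, 24)
    a = ImageFrame(rng.uniform(0, 255, shape))
    b = ImageFrame(rng.uniform(0, 255, shape))
    return a, b


def ssim_bruteforce(x, y, params):
    """Independent SSIM oracle: explicit loop over every valid window.

    Evaluates the SSIM formula per window from weighted moments computed
    directly on the window pixels, then averages. Shares no code with the
    filtering implementation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = params.window_size
    w1 = params.window_weights_1d()
    w2d = np.outer(w1, w1)
    C1, C2 = params.C1, params.C2
    vals = []
    for i in range(x.shape[0] - w + 1):
        for j in range(x.shape[1] - w + 1):
            xs = x[i : i + w, j : j + w]
            ys = y[i : i + w, j : j + w]
            mx = (w2d * xs).sum()
            my = (w2d * ys).sum()
            vx = (w2d * (xs - mx) ** 2).sum()
            vy = (w2d * (ys - my) ** 2).sum()
            cxy = (w2d * (xs - mx) * (ys - my)).sum()
            vals.append(
                ((2 * mx * my + C1) * (2 * cxy + C2))
                / ((mx**2 + my**2 + C1) * (vx + vy + C2))
            )
    return float(np.mean(vals))
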