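import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene(rng):
    from fsikit.instrument import Scene

    return Scene(rng.random((6, 8)), pitch_mm=0.52, modality="fluorescence")


def reference_dither(img):
    """Independent scalar Floyd-Steinberg oracle: serpentine scan, 7/16-3/16-
    5/16-1/16 kernel mirrored on reverse rows, border error dropped,
    threshold >= 0.5, written pixel-by-pixel with explicit ifs."""
    img = [list(map(float, row)) for row in img]
    M = len(img)
    N = len(img[0])
    out = [[0] * N for _ in range(M)]
    for i in range(M):
        cols = range(N) if i % 2 == 0 else range(N - 1, -1, -1)
        step = 1 if i % 2 == 0 else -1
        for j in cols:
            old = img[i][j]
            new = 1.0 if old >= 0.5 else 0.0
            out[i][j] = int(new)
            e = old - new
            if 0 <= j + step < N:
                img[i][j + step] += e * 7.0 / 16.0
            if i + 1 < M:
                if 0 <= j - step < N:
                    img[i + 1][j - step] += e * 3.0 / 16.0
                img[i + 1][j] += e * 5.0 / 16.0
                if 0 <= j + step < N:
                    img[i + 1][j + step] += e * 1.0 / 16.0
    return np.array(out, dtype=np.uint8)


def brute_force_circular_plan(shape, ratio):
    """Enumeration oracle: sort all conjugate-pair classes by wrap-around
    radius (ties by (u, v)), accumulate implied coverage until >= ratio*M*N."""
    M, N = shape
    classes = []
    seen = set()
    for u in range(M):
        for v in range(N):
            if (u, v) in seen:
                continue
            cu, cv = (M - u) % M, (N - v) % N
            seen.add((u, v))
            seen.add((cu, cv))
            r = np.hypot(min(u, M - u), min(v, N - v))
            weight = 1 if (cu, cv) == (u, v) else 2
            members = sorted({(u, v), (cu, cv)})
            classes.append((r, members[0], weight))
    classes.sort()
    target = ratio * (M * N)
    covered = 0
    count = 0
    for _, _, w in classes:
        if covered >= target and count:
            break
        covered += w
        count += 1
    return count
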