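import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_masked_image(rng, shape=(6, 6), levels=6, p_mask=0.7):
    """A small random integer image with a random (non-empty) mask."""
    img = rng.integers(0, levels, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return img, mask


def naive_histogram_features(values):
    """Direct moment summation, independent of the package implementation."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    sd = var ** 0.5
    if sd == 0:
        return mean, 0.0, 0.0, 0.0
    skew = sum((v - mean) ** 3 for v in vals) / n / sd**3
    kurt = sum((v - mean) ** 4 for v in vals) / n / var**2 - 3.0
    return mean, sd, skew, kurt


def naive_glcm(img, mask, offsets, symmetric):
    """Dictionary-based pair enumeration over explicit python loops."""
    img = np.asarray(img)
    mask = np.asarray(mask, bool)
    counts = {}
    nr, nc = img.shape
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc and mask[r2, c2]:
                    a, b = int(round(img[r, c])), int(round(img[r2, c2]))
                    counts[(a, b)] = counts.get((a, b), 0) + 1
                    if symmetric:
                        counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def naive_glcm_features(probs):
    """Feature formulas evaluated cell by cell over a sparse dict GLCM."""
    import math

    asm = sum(p * p for p in probs.values())
    entropy = -sum(p * math.log2(p) for p in probs.values() if p > 0)
    contrast = sum((i - j) ** 2 * p for (i, j), p in probs.items())
    px, py = {}, {}
    for (i, j), p in probs.items():
        px[i] = px.get(i, 0.0) + p
        py[j] = py.get(j, 0.0) + p
    mu_x = sum(i * p for i, p in px.items())
    mu_y = sum(j * p for j, p in py.items())
    var_x = sum((i - mu_x) ** 2 * p for i, p in px.items())
    var_y = sum((j - mu_y) ** 2 * p for j, p in py.items())
    denom = (var_x * var_y) ** 0.5
    if denom == 0:
        corr = 0.0
    else:
        e_xy = sum(i * j * p for (i, j), p in probs.items())
        corr = (e_xy - mu_x * mu_y) / denom
    return asm, entropy, contrast, corr
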