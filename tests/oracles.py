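"""Independent brute-force oracles: plain python/numpy scalar loops, kept
deliberately naive and separate from the implementation they check."""

import numpy as np


def dilated_conv_loop(p: np.ndarray, k: np.ndarray, rate: int) -> np.ndarray:
    """Direct double-loop dilated convolution with zero padding r*rate."""
    kh, kw = k.shape
    rh, rw = (kh - 1) // 2, (kw - 1) // 2
    h, w = p.shape
    out = np.zeros_like(p, dtype=float)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    yy = y + (i - rh) * rate
                    xx = x + (j - rw) * rate
                    if 0 <= yy < h and 0 <= xx < w:
                        acc += p[yy, xx] * k[i, j]
            out[y, x] = acc
    return out


def _fdx(img):
    g = np.zeros_like(img, dtype=float)
    for y in range(img.shape[0]):
        for x in range(img.shape[1] - 1):
            g[y, x] = img[y, x + 1] - img[y, x]
    return g


def _fdy(img):
    g = np.zeros_like(img, dtype=float)
    for y in range(img.shape[0] - 1):
        for x in range(img.shape[1]):
            g[y, x] = img[y + 1, x] - img[y, x]
    return g


def l2_loop(a, b):
    total = 0.0
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            total += (a[y, x] - b[y, x]) ** 2
    return total / a.size


def gradient_loop(a, b):
    gax, gay, gbx, gby = _fdx(a), _fdy(a), _fdx(b), _fdy(b)
    total = 0.0
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            total += abs(gax[y, x] - gbx[y, x]) + abs(gay[y, x] - gby[y, x])
    return total / a.size


def normal_loop(a, b):
    gax, gay, gbx, gby = _fdx(a), _fdy(a), _fdx(b), _fdy(b)
    total = 0.0
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            na = np.array([gax[y, x], gay[y, x], 1.0])
            nb = np.array([gbx[y, x], gby[y, x], 1.0])
            cos = na.dot(nb) / (np.linalg.norm(na) * np.linalg.norm(nb))
            total += 1.0 - cos
    return total / a.size


def rmse_loop(a, b):
    total = 0.0
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            total += (a[y, x] - b[y, x]) ** 2
    return np.sqrt(total / a.size)


def mae_loop(a, b):
    total = 0.0
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            total += abs(a[y, x] - b[y, x])
    return total / a.size


def psnr_loop(a, b, peak=4095.0):
    return 20.0 * np.log10(peak / rmse_loop(a, b))


def ssim_loop(a, b, window=11, sigma=1.5, k1=0.01, k2=0.03, peak=4095.0):
    """Per-window scalar loop over Gaussian-weighted moments (valid mode)."""
    half = window // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    win = np.outer(g, g)
    win /= win.sum()
    c1, c2 = (k1 * peak) ** 2, (k2 * peak) ** 2
    h, w = a.shape
    vals = []
    for y in range(h - window + 1):
        for x in range(w - window + 1):
            wa = a[y:y + window, x:x + window]
            wb = b[y:y + window, x:x + window]
            mu_a = (win * wa).sum()
            mu_b = (win * wb).sum()
            var_a = (win * wa * wa).sum() - mu_a ** 2
            var_b = (win * wb * wb).sum() - mu_b ** 2
            cov = (win * wa * wb).sum() - mu_a * mu_b
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                        / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))
    return float(np.mean(vals))


def lsgan_loop(real, fake):
    d = 0.5 * np.mean((np.asarray(real) - 1.0) ** 2) + 0.5 * np.mean(np.asarray(fake) ** 2)
    g = np.mean((np.asarray(fake) - 1.0) ** 2)
    return d, g


def cycle_identity_loop(g_ab, g_ba, a, b):
    e_cyc = np.mean(np.abs(g_ba(g_ab(a)) - a)) + np.mean(np.abs(g_ab(g_ba(b)) - b))
    e_iden = np.mean(np.abs(g_ab(b) - b)) + np.mean(np.abs(g_ba(a) - a))
    return e_cyc, e_iden


def numerical_gradient(fn, arr, eps=1e-6):
    """Central-difference gradient of a scalar function of one array."""
    grad = np.zeros_like(arr, dtype=float)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        hi = fn(arr)
        arr[idx] = orig - eps
        lo = fn(arr)
        arr[idx] = orig
        grad[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return grad
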