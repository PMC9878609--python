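"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def brute_force_ssim(a, b, width, sd, k1, k2, dynamic_range):
    """Windowed SSIM computed directly from the definition (explicit loops)."""
    ax = np.arange(width) - (width - 1) / 2.0
    g = np.exp(-0.5 * (ax / sd) ** 2)
    kern = g[:, None, None] * g[None, :, None] * g[None, None, :]
    kern = kern / kern.sum()
    c1, c2 = (k1 * dynamic_range) ** 2, (k2 * dynamic_range) ** 2
    scores = []
    nx, ny, nz = a.shape
    for i in range(nx - width + 1):
        for j in range(ny - width + 1):
            for k in range(nz - width + 1):
                wa = a[i : i + width, j : j + width, k : k + width]
                wb = b[i : i + width, j : j + width, k : k + width]
                mu_a = (kern * wa).sum()
                mu_b = (kern * wb).sum()
                va = (kern * wa * wa).sum() - mu_a**2
                vb = (kern * wb * wb).sum() - mu_b**2
                cov = (kern * wa * wb).sum() - mu_a * mu_b
                num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
                den = (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
                scores.append(num / den)
    return float(np.mean(scores))
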