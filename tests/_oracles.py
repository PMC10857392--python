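"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over the defining formulas, kept
deliberately separate from the vectorised package code it checks.
"""

import math

import numpy as np


def rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def waveform_length(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def mav(x):
    return sum(abs(v) for v in x) / len(x)


def zero_crossings(x, eps=0.0):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps:
            count += 1
    return count


def slope_sign_changes(x, eps=0.0):
    count = 0
    for i in range(1, len(x) - 1):
        d1 = x[i] - x[i - 1]
        d2 = x[i] - x[i + 1]
        if d1 * d2 > 0 and max(abs(d1), abs(d2)) >= eps:
            count += 1
    return count


def biased_autocorr(x, maxlag):
    n = len(x)
    return [sum(x[i] * x[i + k] for i in range(n - k)) / n for k in range(maxlag + 1)]


def ar_levinson_durbin(x, order=4):
    """Yule-Walker AR coefficients and prediction-error variance via the
    Levinson-Durbin recursion on the biased autocorrelation."""
    r = biased_autocorr(x, order)
    a = [0.0] * order
    e = r[0]
    for m in range(1, order + 1):
        acc = r[m]
        for k in range(1, m):
            acc -= a[k - 1] * r[m - k]
        refl = acc / e
        new_a = a[:]
        new_a[m - 1] = refl
        for k in range(1, m):
            new_a[k - 1] = a[k - 1] - refl * a[m - 1 - k]
        a = new_a
        e *= 1.0 - refl * refl
    return a, e


def mean_amplitude_spectrum(x):
    """Mean one-sided DFT magnitude of the Hann-tapered frame, via a direct
    O(n^2) DFT."""
    n = len(x)
    taper = [0.5 * (1.0 - math.cos(2.0 * math.pi * i / (n - 1))) for i in range(n)]
    xt = [x[i] * taper[i] for i in range(n)]
    mags = []
    for k in range(n // 2 + 1):
        re = sum(xt[i] * math.cos(2.0 * math.pi * k * i / n) for i in range(n))
        im = -sum(xt[i] * math.sin(2.0 * math.pi * k * i / n) for i in range(n))
        mags.append(math.hypot(re, im))
    return sum(mags) / len(mags)


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    sxx = sum((v - mx) ** 2 for v in x)
    syy = sum((v - my) ** 2 for v in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def moments(x):
    """(mean, population std, skewness, excess kurtosis) via plain loops."""
    n = len(x)
    m = sum(x) / n
    m2 = sum((v - m) ** 2 for v in x) / n
    m3 = sum((v - m) ** 3 for v in x) / n
    m4 = sum((v - m) ** 4 for v in x) / n
    return m, math.sqrt(m2), m3 / m2**1.5, m4 / m2**2 - 3.0


def ols_log_fit(x, y):
    """Closed-form least squares of y on ln(x): (slope, intercept, R^2)."""
    lx = [math.log(v) for v in x]
    n = len(x)
    mx = sum(lx) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in lx)
    sxy = sum((lx[i] - mx) * (y[i] - my) for i in range(n))
    slope = sxy / sxx
    intercept = my - slope * mx
    ssres = sum((y[i] - slope * lx[i] - intercept) ** 2 for i in range(n))
    sstot = sum((v - my) ** 2 for v in y)
    r2 = 1.0 if sstot == 0 else 1.0 - ssres / sstot
    return slope, intercept, r2


def subband_rms_oracle(x, fs, low, high):
    """RMS of the band-passed frame; the filter itself is shared with the
    implementation (an IIR zero-phase filter has no simple closed form),
    the RMS reduction is looped."""
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, np.asarray(x, dtype=float))
    return rms(list(y))
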