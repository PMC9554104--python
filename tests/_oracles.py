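"""Independent oracles used by the test suite.

Each oracle is a deliberately naive transcription of the definition it
checks (explicit loops, pairwise enumeration, closed-form CDFs) and shares
no code path with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import lognorm


# ---------------------------------------------------------------- counts ---

def counts_oracle_axis(x, b, a, gain, *, rate_in=50.0, rate_mid=30.0,
                       rate_out=10.0, deadband=0.068, saturation=2.13,
                       quantization=0.01664, settle_s=5.0):
    """Straight-line, sample-by-sample transcription of the count chain."""
    # linear resample to 30 Hz
    n_mid = int(math.floor(len(x) / rate_in * rate_mid))
    x30 = []
    for k in range(n_mid):
        t = k / rate_mid
        i = int(math.floor(t * rate_in))
        if i >= len(x) - 1:
            x30.append(x[-1])
        else:
            frac = t * rate_in - i
            x30.append(x[i] * (1 - frac) + x[i + 1] * frac)
    # pad with first value, run the IIR difference equation directly
    n_pad = int(round(settle_s * rate_mid))
    xs = [x30[0]] * n_pad + x30
    bg = [bi * gain for bi in b]
    y = [0.0] * len(xs)
    for n in range(len(xs)):
        acc = 0.0
        for k in range(len(bg)):
            if n - k >= 0:
                acc += bg[k] * xs[n - k]
        for k in range(1, len(a)):
            if n - k >= 0:
                acc -= a[k] * y[n - k]
        y[n] = acc / a[0]
    y = y[n_pad:]
    # decimate, rectify, deadband, saturate, quantize
    step = int(round(rate_mid / rate_out))
    units = []
    for v in y[::step]:
        v = abs(v)
        if v < deadband:
            v = 0.0
        if v > saturation:
            v = saturation
        units.append(math.floor(v / quantization))
    # sum per epoch
    per_epoch = int(round(rate_out))
    n_epochs = int(math.floor(len(x) / rate_in))
    return [sum(units[k * per_epoch:(k + 1) * per_epoch])
            for k in range(n_epochs)]


# ------------------------------------------------------------------- ROC ---

def auc_pairwise(counts, labels):
    """AUC by exhaustive pair counting, ties worth one half."""
    pos = [c for c, l in zip(counts, labels) if l == 1]
    neg = [c for c, l in zip(counts, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def youden_bruteforce(counts, labels):
    """Exhaustive search of the Youden-optimal '>=' cutoff over observed values.

    Returns (cutoff, sensitivity, specificity); objective ties resolve to the
    smallest cutoff, with +inf (classify nothing functional) as a candidate.
    """
    pos = [c for c, l in zip(counts, labels) if l == 1]
    neg = [c for c, l in zip(counts, labels) if l == 0]
    best = None
    for c in sorted(set(counts)) + [float("inf")]:
        sens = sum(1 for p in pos if p >= c) / len(pos)
        spec = sum(1 for q in neg if q < c) / len(neg)
        j = sens + spec
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    return best[1], best[2], best[3]


def auc_pairwise_vectorized(counts, labels):
    """Exhaustive pairwise AUC via a full comparison matrix (no ranking)."""
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = counts[labels == 1][:, None]
    neg = counts[labels == 0][None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum())
                 / (pos.size * neg.size))


def youden_bruteforce_vectorized(counts, labels):
    """Exhaustive Youden search over every observed value, by broadcasting."""
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = counts[labels == 1]
    neg = counts[labels == 0]
    cands = np.concatenate([np.unique(counts), [np.inf]])
    sens = (pos[None, :] >= cands[:, None]).mean(axis=1)
    spec = (neg[None, :] < cands[:, None]).mean(axis=1)
    j = sens + spec
    i = int(np.argmax(j))  # first maximum = smallest cutoff
    return float(cands[i]), float(sens[i]), float(spec[i])


def youden_true_mixture(zm_pos, mu_pos, sg_pos, zm_neg, mu_neg, sg_neg,
                        grid_max=500.0, grid_n=200000):
    """Numeric Youden search on the true zero-inflated log-normal CDFs."""
    c = np.linspace(1e-3, grid_max, grid_n)
    sens = 1 - (zm_pos + (1 - zm_pos) * lognorm.cdf(c, s=sg_pos, scale=np.exp(mu_pos)))
    spec = zm_neg + (1 - zm_neg) * lognorm.cdf(c, s=sg_neg, scale=np.exp(mu_neg))
    i = int(np.argmax(sens + spec))
    return float(c[i]), float(sens[i]), float(spec[i])


# ------------------------------------------------------------ evaluation ---

def tally_oracle(predictions, truth):
    """One-pass tally-and-divide of the five performance measures."""
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, truth):
        if p and t == 1:
            tp += 1
        elif p and t == 0:
            fp += 1
        elif not p and t == 0:
            tn += 1
        else:
            fn += 1
    div = lambda a, b: a / b if b else float("nan")
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "accuracy": div(tp + tn, tp + fp + tn + fn),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
    }
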