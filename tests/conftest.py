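"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from redcam.pipeline import RunConfig, run_study
from redcam.scene import default_chart, render_chart, render_eye


@pytest.fixture(scope="session")
def chart():
    return default_chart()


@pytest.fixture(scope="session")
def chart_scene(chart):
    return render_chart(chart, patch_px=16)


@pytest.fixture(scope="session")
def small_eye():
    """A 96-px conjunctiva scene with ~20% vessel coverage."""
    return render_eye("S1", 0.2, size=96, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """One full default study run shared by pipeline and acceptance tests."""
    return run_study(RunConfig(seed=1))


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def loop_score_oracle(rgb, include_mask, red_band=(330.0, 30.0), chroma_floor=0.01):
    """Per-pixel Python-loop version of the four redness metrics."""
    rel = 0.0
    rg = 0.0
    rb = 0.0
    red = 0
    n = 0
    h_img, w_img = rgb.shape[:2]
    for y in range(h_img):
        for x in range(w_img):
            if not include_mask[y, x]:
                continue
            n += 1
            r, g, b = (float(v) for v in rgb[y, x])
            s = r + g + b
            if s > 0:
                rel += r / s
            rg += r - g
            rb += r - b
            mx, mn = max(r, g, b), min(r, g, b)
            c = mx - mn
            if c >= chroma_floor:
                if mx == r:
                    hue = 60.0 * (((g - b) / c) % 6.0)
                elif mx == g:
                    hue = 60.0 * ((b - r) / c + 2.0)
                else:
                    hue = 60.0 * ((r - g) / c + 4.0)
                lo, hi = red_band
                in_band = (hue >= lo or hue < hi) if lo > hi else (lo <= hue < hi)
                if in_band:
                    red += 1
    return rel, rg / n, rb / n, red / n, n


def brute_force_rm_anova(arr):
    """Explicit nested-sum SS decomposition for a balanced design.

    ``arr`` has axis 0 = subject, axes 1.. = within factors.  Returns
    {frozenset(axes): (ss, df)} for every nonempty axis subset, computed
    from cell means with plain Python loops (no shared code with the
    implementation under test).
    """
    shape = arr.shape
    ndim = arr.ndim
    axes = list(range(ndim))
    means = {}
    for k in range(ndim + 1):
        for sub in itertools.combinations(axes, k):
            acc = {}
            counts = {}
            for idx in itertools.product(*(range(s) for s in shape)):
                key = tuple(idx[a] for a in sub)
                acc[key] = acc.get(key, 0.0) + float(arr[idx])
                counts[key] = counts.get(key, 0) + 1
            means[sub] = {k_: acc[k_] / counts[k_] for k_ in acc}
    out = {}
    for k in range(1, ndim + 1):
        for sub in itertools.combinations(axes, k):
            ss = 0.0
            for idx in itertools.product(*(range(shape[a]) for a in sub)):
                effect = 0.0
                for j in range(len(sub) + 1):
                    for inner in itertools.combinations(range(len(sub)), j):
                        inner_axes = tuple(sub[i] for i in inner)
                        inner_idx = tuple(idx[i] for i in inner)
                        sign = (-1) ** (len(sub) - j)
                        effect += sign * means[inner_axes][inner_idx]
                ss += effect**2
            n_per = 1
            for a in axes:
                if a not in sub:
                    n_per *= shape[a]
            df = 1
            for a in sub:
                df *= shape[a] - 1
            out[frozenset(sub)] = (ss * n_per, df)
    return out


def random_long_dataset(rng, n_subjects=4):
    """A random balanced 2 (arm) × 3 (camera) × 2 (lighting) × 2 (mag) table."""
    import pandas as pd

    rows = []
    for s in range(n_subjects):
        for arm in ("pre", "post"):
            for cam in ("c1", "c2", "c3"):
                for light in ("high", "low"):
                    for mag in (6, 10):
                        rows.append(
                            {
                                "subject": f"S{s}",
                                "processing_arm": arm,
                                "camera": cam,
                                "lighting": light,
                                "magnification": mag,
                                "value": rng.normal(),
                            }
                        )
    return pd.DataFrame(rows)
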