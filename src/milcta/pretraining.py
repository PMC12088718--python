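"""Shape-primitive surrogate pretraining for the slice encoder.

The reference training protocol relies on transfer learning: an encoder whose
filters already respond to generic image structure, so that attention over
weakly labelled bags only has to learn *which* slices matter, not how to see.
Without external pretrained weights, the same role is played by a
procedurally generated pretext corpus: sparse edge-style images containing a
random curvilinear outline (the look of a vessel boundary after edge-fusion
preprocessing), half of which additionally contain one small compact blob
outline — a generic "focal structure on a curvilinear structure" primitive.
The encoder is pretrained to detect the blob on this corpus, which involves
no patient data and no cohort labels, and is then fine-tuned end-to-end by
the MIL objective.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._autograd import Tensor
from ._nn import Adam, Dense, Module, bce_with_logits


def make_pretext_image(rng: np.random.Generator, size: int = 48) -> tuple[np.ndarray, int]:
    """One pretext sample: curvilinear outline ± a compact blob outline.

    Returns the image (float32 in [0,1]) and the blob-presence label.
    """
    h = w = size
    img = np.zeros((h, w), dtype=np.float32)
    m = max(3, size // 12)
    p0 = np.array([rng.uniform(m, h - m), 0.0])
    p2 = np.array([rng.uniform(m, h - m), w - 1.0])
    p1 = np.array([rng.uniform(0, h), rng.uniform(0.25 * w, 0.75 * w)])
    t = np.linspace(0, 1, 4 * w)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    ij = np.clip(np.round(pts).astype(int), 0, [h - 1, w - 1])
    raster = np.zeros((h, w), bool)
    raster[ij[:, 0], ij[:, 1]] = True
    dist = ndimage.distance_transform_edt(~raster)
    halfwidth = rng.uniform(0.025 * size, 0.067 * size)
    band = dist <= halfwidth
    outline = band & ~ndimage.binary_erosion(band)
    img[outline] = rng.uniform(0.35, 0.8)
    label = int(rng.random() < 0.5)
    if label:
        k = int(rng.uniform(0.3, 0.7) * len(pts))
        anchor = pts[k]
        tangent = pts[min(k + 8, len(pts) - 1)] - pts[max(k - 8, 0)]
        normal = np.array([-tangent[1], tangent[0]])
        normal /= np.linalg.norm(normal) + 1e-9
        offset = rng.choice([-1.0, 1.0]) * rng.uniform(0, halfwidth + 1.5)
        c = np.clip(anchor + normal * offset, 3, [h - 4, w - 4])
        rr, cc = np.mgrid[0:h, 0:w]
        r1, r2 = rng.uniform(0.033 * size, 0.067 * size, size=2)
        ellipse = ((rr - c[0]) / max(r1, 1.2)) ** 2 + ((cc - c[1]) / max(r2, 1.2)) ** 2 <= 1.0
        eout = ellipse & ~ndimage.binary_erosion(ellipse)
        img[eout] = rng.uniform(0.35, 0.8)
    speckle = rng.random((h, w)) < rng.uniform(0, 0.003)
    img[speckle] = rng.uniform(0.3, 0.6)
    return img, label


def generate_pretext_dataset(n: int, size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    X = np.empty((n, 1, size, size), dtype=np.float32)
    y = np.empty(n, dtype=int)
    for i in range(n):
        X[i, 0], y[i] = make_pretext_image(rng, size)
    return X, y


def pretrain_encoder(
    encoder: Module,
    embed_dim: int,
    input_size: tuple[int, int],
    rng: np.random.Generator,
    n_images: int = 2000,
    epochs: int = 6,
    batch_size: int = 64,
    lr: float = 3e-3,
    l2: float = 1e-4,
) -> list[float]:
    """Train the encoder on the pretext corpus through a throwaway head.

    Only square pretext images are generated; rectangular inputs use the
    smaller side.  Returns the per-epoch pretext losses.
    """
    size = min(input_size)
    X, y = generate_pretext_dataset(n_images, size, rng)
    head = Dense(embed_dim, 1, rng)
    params = encoder.parameters() + head.parameters()
    opt = Adam(params, lr=lr, l2=l2)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n_images)
        total = 0.0
        for start in range(0, n_images, batch_size):
            idx = order[start : start + batch_size]
            feats = encoder(Tensor(X[idx]))
            logits = head(feats.relu()).reshape(len(idx))
            loss = bce_with_logits(logits, y[idx])
            for p in params:
                p.grad = None
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        losses.append(total / n_images)
    return losses
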