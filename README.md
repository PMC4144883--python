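# pefi — spatial-uncertainty texture features for image classification

`pefi` extracts texture features that quantify *two* kinds of uncertainty in
a grayscale image window at once: the **imprecision** of its gray-level
content (modeled with fuzzy sets) and the **spatial randomness** of where
those gray levels sit (modeled with geostatistics).  The resulting feature —
the entropy of a fuzzy event with respect to an indicator-kriged probability
field — discriminates textures that plain intensity statistics cannot, e.g.
organelle-bearing vs. empty regions in electron-microscopy scans of cells,
or tissue types on CT, where class differences live in spatial correlation
structure rather than in the histogram.

## The feature

For an image window with gray levels x(u) ∈ [0, 1] at pixel locations u:

1. **Fuzzy c-means** partitions the gray levels into c clusters by
   minimizing J_m = Σᵢ Σₖ u_ik^m ‖xᵢ − v_k‖² subject to Σₖ u_ik = 1,
   yielding membership grades μₖ(u) and ascending centers v₁ < … < v_c.
2. **Indicator coding**: for each cluster k and level cut α ∈ (0, 1], pixel
   u is coded i(u; k, α) = 1 iff μₖ(u) ≥ α.
3. **Indicator kriging**: every pixel is treated as unsampled and its class
   probability F̂(u; k, α) = Σⱼ wⱼ · i(uⱼ; k, α) is estimated from its K
   nearest neighbors.  The weights wⱼ solve the ordinary-kriging system
   (unit-sum constraint, one Lagrange multiplier) built on the window's own
   experimental indicator semivariogram
   γ̂(h) = (1/2N(h)) Σ (i(u) − i(u+h))²; the universal-kriging variant adds
   polynomial drift constraints Σⱼ wⱼ f_l(uⱼ) = f_l(u) with
   f ∈ {1, r, c} (degree 1) or {1, r, c, r², rc, c²} (degree 2) to handle a
   locally varying mean.
4. **Fuzzy-event entropy**: the kriged values are normalized into a
   distribution pᵢ over the window and the feature entry is
   H(μₖ; P_α) = −Σᵢ μₖ(xᵢ) pᵢ log₂ pᵢ, with 0·log 0 := 0.

Entries over all (cluster, α) pairs — cluster-major, α ascending — form one
feature vector per window (length c · |α|).  **PEFI1** denotes the
ordinary-kriging variant, **PEFI2** the universal-kriging one.  Windows are
classified by nearest-prototype matching (Euclidean or Mahalanobis with a
pooled within-class covariance) or k-NN.

## Worked example

Two synthetic 32×32 textures with *identical* intensity histograms (equal
areas of gray levels 0.2 and 0.8, noise sd 0.05) but different spatial
correlation scales (1 vs. 6 pixels):

```python
import numpy as np
from pefi import TextureSpec, generate_texture, pefi_features

fine = generate_texture(TextureSpec(kind="binary-mosaic", shape=(32, 32),
                                    correlation_scale=1.0, intensity_levels=(0.2, 0.8),
                                    noise_sd=0.05, seed=7))
coarse = generate_texture(TextureSpec(kind="binary-mosaic", shape=(32, 32),
                                      correlation_scale=6.0, intensity_levels=(0.2, 0.8),
                                      noise_sd=0.05, seed=7))
for name, img in (("fine", fine), ("coarse", coarse)):
    vec = pefi_features(img, c=2, m=2.0, alphas=(0.5, 0.6, 0.7, 0.8, 0.9),
                        k_neighbors=5, method="OK", seed=0)
    print(name, np.array2string(vec.entries, precision=3))
```

prints

```
fine [7.226 7.226 7.226 7.226 7.223 7.223 7.223 7.223 7.223 7.223]
coarse [8.695 8.695 8.695 8.695 8.693 8.71  8.71  8.71  8.71  8.71 ]
```

The ten entries are the entropies H(μₖ; P_α) for k ∈ {0, 1} × α ∈
{0.5, …, 0.9} in bits (upper bound log₂ 1024 = 10 for a 32×32 window).  The
fine texture's kriged probabilities concentrate on the speckled cluster
boundaries, giving a lower entropy than the coarse texture, whose
probability mass spreads almost uniformly across its large blobs — the two
classes separate even though their histograms match.

The same experiment end to end — 40 windows per class, feature extraction
with both kriging variants, nearest-prototype classification over 10
stratified 50/50 Monte-Carlo splits:

```bash
pefi bench --out-dir bench_out --seed 1
```

```json
{
  "pefi1": 100.0,
  "pefi2": 100.0
}
```

(mean test accuracy in percent; `bench_out/` holds the feature tables,
dataset manifest and full metrics).  The CLI also provides `synth`,
`extract`, `classify` and `evaluate` subcommands for running the pipeline
on image files; see `pefi --help`.

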