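# imfid — informative IMF identification for multichannel signals

`imfid` decides, without prior knowledge of the frequency bands of interest,
which intrinsic mode functions (IMFs) of a multichannel signal carry
channel-specific information and which are indistinguishable from noise.
It is aimed at EEG / brain–computer-interface work — where task-related
sensorimotor rhythms hide in a handful of oscillatory scales — but applies
to any multichannel time series.

## Method

1. **NA-MEMD.** The n-channel signal is augmented with l independent white
   Gaussian noise channels and decomposed jointly by multivariate empirical
   mode decomposition: s(t) = Σ_j d_j(t) + r(t). The noise channels
   exploit MEMD's quasi-dyadic filter-bank behaviour on white noise, so
   scale j means the same frequency band in every channel.
2. **Composite groups.** At each scale j and signal channel i, the channel's
   IMF is stacked with the l noise-channel IMFs: l+1 waveforms of length L.
3. **Kernel spectral regression.** A p-nearest-neighbour affinity graph over
   the l+1 waveforms yields graph-eigenproblem responses v; a Gaussian-kernel
   ridge regression (K + αI)a = v learns the embedding map, and
   Z = K a places the waveforms in an M-dimensional subspace (M = 2).
4. **GMM–MDL clustering.** A Gaussian mixture is fitted to Z by EM,
   components are agglomeratively merged, and the cluster count ĉ minimizing
   Rissanen's minimum description length

   MDL(c, Ω) = −Σ_i log Σ_k π_k N(z_i; μ_k, Σ_k) + ½ υ log(NM)

   is selected (υ = c(M + M(M+1)/2 + 1) − 1). The signal IMF is
   **informative** iff its maximum-likelihood cluster contains no noise IMF.
5. **Downstream.** Informative IMFs are summed into a reconstructed signal;
   common spatial patterns (generalized eigenvectors of the class
   covariances, C₁u = ζC₂u) extract normalized log-variance features
   f_j = log(var(ŝ_j)/Σ var(ŝ_i)); a cross-validated Gaussian-kernel SVM
   classifies motor-imagery trials.

## Worked example

The built-in simulation generates a 3-channel signal (fs = 1000 Hz,
L = 1000) of unit sinusoids at 12, 26 and 50 Hz — X carries all three
tones, Y omits 26 Hz, Z omits 12 Hz — plus white noise at 20 dB SNR:

```python
from imfid import generate_eq7_signal, identify_all, SIM_PRESET
from imfid.signals import NoiseSpec

sig = generate_eq7_signal(noise_snr_db=20.0, L=1000, fs=1000.0, seed=1)
noise = NoiseSpec(kind="white", l=15, snr_db=6.1, seed=10001)
mask = identify_all(sig, noise, SIM_PRESET)
for ch, name in enumerate("XYZ"):
    print(name, mask.informative_scales(ch))
```

prints

```
X [4, 5, 6]
Y [4, 6]
Z [4, 5]
```

i.e. the 50, 26 and 12 Hz tones are found on scales 4, 5 and 6 of the
decomposition, exactly the scales where the dyadic filter bank
(≈ 31–62, 16–31, 8–16 Hz at fs = 1000) places them; Y and Z lack the scale
of the tone each omits. All other scales cluster into a single class and
are rejected as noise-like.

The same machinery runs from the shell:

```bash
imfid simulate --snr-db 20 --seed 1 --output sig.h5
imfid identify --input sig.h5 --preset sim --seed 7 --output mask.json
imfid evaluate --noise red --levels 0,5,10,20 --trials 10 --output report.json
```

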