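# endoleakseg

Detection of endoleaks on post-EVAR CT angiography (CTA), built around a
lesion-aware training augmentor.

After endovascular aortic repair (EVAR), surveillance CTA must be checked for
endoleak — persistent flow outside the stent graft but inside the aneurysm
sac, visible as a contrast-bright region within the mid-intensity sac.
`endoleakseg` provides the full pipeline: cohort I/O (DICOM series, NIfTI
label volumes, an HDF5 store), a synthetic phantom generator with exact
ground-truth masks, deterministic preprocessing, a compact encoder–decoder
segmentation network, slice-threshold/size-filter/case-ensemble
post-processing, and bootstrap evaluation.

## The core idea

Endoleak and sac-thrombus pixels are modelled as Gaussians in Hounsfield
units, fit by pooling labeled training pixels: endoleak ~ N(u_e, σ_e²), sac
~ N(u_a, σ_a²). The **lesion augmentor** then manufactures paired training
examples in native HU:

* *add*: a random-shaped blob bounded by the aneurysm-sac mask (outside the
  stent lumen) is filled with N(u_e, σ_e²) draws and becomes the target;
* *remove*: pixels under the endoleak mask are replaced with N(u_a, σ_a²)
  draws and the target becomes empty.

Everything outside the lesion is untouched, so each pair is anatomically
identical except for the lesion — the network must learn the lesion itself.
Per-slice probability maps are binarised at a validation-optimised threshold,
cleaned by an inclusive component-area filter, and aggregated into a case
decision (a run of k consecutive positive slices, default k = 2).

## Worked example

```python
import endoleakseg as es

cohort = es.generate_cohort(es.PhantomConfig(seed=11), 50, 20)
split = es.split_cohort(cohort, 32, 8, 8, 2, 10, 10, seed=7)
tr, va, te = (es.select_cases(cohort, s)
              for s in (split.train, split.validation, split.test))

det = es.EndoleakDetector(
    tr, va, model_config=es.ModelConfig(seed=0, epochs=10, learning_rate=3e-3))
res = det.fit()
print(res.summary(res.evaluate(te, n_boot=1000, seed=0)))
```

```
Endoleak Detection Results
==========================================================
Encoder-decoder depth 3, base channels 8, input 64x64
Epochs trained: 10   best val F1: 0.899
Operating threshold (val-optimised): 0.90 (val slice F1 1.000)
Size filter: [10, 819] px; case rule: run k=2
Intensity model: leak 180.1±26.6 HU (n=7317), sac 40.0±15.6 HU (n=211617)
----------------------------------------------------------
Per-slice AUC:   1.000
Per-case accuracy 100.0%  precision 100.0%  recall 100.0%
Bootstrap SD of accuracy: 0.0 points
```

The intensity model recovers the phantom's configured palette (leak
180 ± √(25²+10²) ≈ 26.9 HU once additive noise is folded in); the operating
threshold is the validation F1 argmax; and on the 20 held-out phantom cases
every slice and case is classified correctly.

The same pipeline is scriptable from the shell:

```sh
endoleakseg simulate --n-pos 50 --n-neg 20 --seed 1 --out cohort.h5
endoleakseg train --cohort cohort.h5 --seed 0 --out model/
endoleakseg evaluate --model model/ --cohort cohort.h5 --out report.json
```

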