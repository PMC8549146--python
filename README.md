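# prostacc

**CBCT-based dose accumulation for prostate SIB radiotherapy, on synthetic
pelvic phantoms with known ground truth.**

In image-guided prostate radiotherapy the *planned* dose is computed once,
on the planning CT — but the patient's anatomy (bladder and rectum filling,
prostate position) differs at every one of the 33 treatment fractions.  The
dose that is actually *delivered* to a target can therefore deviate from
the plan, and the structure most at risk is the dominant intraprostatic
lesion (DIL): when it sits dorsally, against the rectum, it lives on the
steep dose gradient that spares that organ.  `prostacc` implements the
full workflow that quantifies this, for researchers studying dose
accumulation and adaptive radiotherapy who want a controlled, fully
synthetic testbed where the ground-truth deformation of every fraction is
known in closed form.

The pipeline, per patient:

1. **Phantom cohort** — a male-pelvis phantom (prostate, seminal vesicles,
   DIL, rectum with gas lumen, bladder, femoral heads, penile bulb) plus
   per-fraction CBCT-like volumes: analytic organ-filling deformations,
   3-DOF couch-shift setup errors (SD ≈ 2.7–2.9 mm per axis), HU noise and
   bias fields.  CBCTs on fractions 1–5 and then every third fraction.
2. **Density override** — a five-level step table (air, lung,
   adipose/soft tissue, cartilage/bone, prosthesis) applied identically to
   planning CT and CBCTs.
3. **Planning** — margin-based target construction
   (PTV_Boost = CTV ⊕ 5 mm minus rectum; PTV = CTV ⊕ 10 mm, 7 mm dorsal)
   and an analytic SIB dose engine with per-fraction dose

       D(x) = A(x) · [1.82·g(δ_PTV) + 0.49·g(δ_Boost)] · [1 − s·e^(−δ_rectum²/2σ²)]

   g a Gaussian penumbra (σ = 3 mm), A a density-driven attenuation
   factor, and a rectum-sparing notch that pulls the boost-edge dose at
   the rectal wall down to the low dose level.
4. **Registration** — rigid alignment from the recorded couch shift, then
   multi-resolution diffusion-regularized demons registration of the
   density-overridden CBCT to the reference CT, yielding the deformation
   vector field (DVF).
5. **Accumulation** — per-fraction dose pulled back through the DVF onto
   the reference CT and summed over the course; unimaged fractions reuse
   the previous CBCT.
6. **Endpoints & statistics** — DVH metrics (D_Mean, D02%, D95%, D98%),
   paired planned-vs-delivered tests with Shapiro–Wilk-gated test choice
   (paired t vs Wilcoxon signed-rank with an exact tie-aware null), an
   unpaired t comparison of dorsal (PZpm) vs ventral lesion dose with 95 %
   CI and Cohen's d, and couch-shift distribution summaries.

See `docs/methods.md` for model details, assumptions and limitations.

## Worked example

One dorsal and one ventral patient, full 33-fraction courses:

```python
import prostacc as pa

cohort = pa.generate_cohort(2, pa.PhantomConfig(), seed=7,
                            sectors=["PZpm", "ventral"])
for sim in cohort:
    res = pa.run_patient(sim)
    m = res.metrics.set_index(["structure", "metric"])
    print(f"patient {sim.seed} ({res.sector_classified:7s})  "
          f"PTV_DIL D_Mean planned {m.loc[('PTV_DIL','DMean'),'planned_gy']:6.2f} Gy  "
          f"delivered {m.loc[('PTV_DIL','DMean'),'delivered_gy']:6.2f} Gy  "
          f"PTV_Boost delivered {m.loc[('PTV_Boost','DMean'),'delivered_gy']:6.2f} Gy")
```

prints

```
patient 7 (dorsal )  PTV_DIL D_Mean planned  72.07 Gy  delivered  72.70 Gy  PTV_Boost delivered  75.59 Gy
patient 8 (ventral)  PTV_DIL D_Mean planned  76.23 Gy  delivered  76.28 Gy  PTV_Boost delivered  75.39 Gy
```

The ventral lesion sits on the flat boost plateau and receives the full
76.23 Gy boost prescription (33 × 2.31 Gy); the dorsal lesion, adjacent to
the rectum, is planned ~4 Gy cooler because of the rectum-sparing gradient
and stays cooler in the delivered dose.  Inter-fraction motion moves its
edge voxels across that gradient, so its delivered mean wanders around the
planned value while the ventral lesion barely changes.  `pa.run_cohort(n,
seed=...)` scales this to a cohort and returns the paired endpoint table,
the dorsal-vs-ventral group comparison and the couch-shift summary.

A command-line interface wraps the same pipeline:

```bash
prostacc simulate -n 2 -s 7 --out sim/     # phantom cohort + manifest (NIfTI/JSON)
prostacc run -n 10 -s 0 --out run/         # simulate + accumulate + metrics CSV
prostacc report --in run/ --out report/    # endpoint table, group stats, shifts
```

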