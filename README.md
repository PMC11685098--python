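# curiomap

Analysis toolkit for studying how momentary **curiosity states** shape
**spatial exploration** and the precision of the **cognitive maps** people
form of explored places.

Participants roam virtual rooms while their position and head direction are
logged; after each room they rate their curiosity and interest and later draw
a sketch map of the room. `curiomap` turns those logs into:

* **Roaming entropy (RE)** — normalised Shannon entropy of the occupancy
  distribution, for both the walking path (over the room's accessible 0.5 m
  grid cells) and head direction (over 10°×10° yaw/pitch bins, k = 648).
  RE is 0 when all time is spent in one bin and 1 at uniform coverage.
* **Sketch-map scores** — two-rater composites over four dimensions (object
  presence, spatial distortion, relative positioning, spatial proportion),
  with intraclass reliability and Cronbach's alpha.
* **Bayesian multilevel models** — a bivariate model of path and
  head-direction RE on within/between-person curiosity and interest, trait
  moderation of the curiosity–coverage link, a cognitive-map precision model,
  and a within-person mediation analysis (curiosity → coverage → map
  precision). Posteriors are summarised by the mean and 93% highest-density
  interval.
* **Synthetic cohorts** — an agent-based walker whose latent drives produce
  the behavioural signatures above, and a linear generator whose ground-truth
  coefficients make parameter recovery exactly checkable.

## Quick start

Run the whole pipeline on a small synthetic cohort:

```bash
curiomap run-all --out results --seed 0
curiomap report results
```

or stage by stage:

```bash
curiomap simulate --participants 6 --rooms 4 --seed 0 --out dataset
curiomap entropy dataset/trajectories.csv dataset/masks --out re_table.csv
curiomap score dataset/sketch_scores.csv --out composites.csv
curiomap fit dataset --model exploration --preset reduced --seed 0
curiomap mediate dataset --preset reduced --seed 0
```

From Python:

```python
import curiomap as cm

room = cm.generate_room(seed=1, occlusion_fraction=0.3)
traj = cm.simulate_trajectory(room, drive=1.0, scan_rate=0.5,
                              duration_s=30.0, cfg=cm.SimConfig(), seed=0)
res = cm.compute_trial_re(traj, room)
print(f"path RE {res.path_re:.3f}, head RE {res.head_re:.3f}")
```

On a known-coefficient synthetic cohort (60 participants × 16 rooms,
ground-truth within-person effects 0.0039 curiosity→path-RE and 0.0058
interest→head-RE), the exploration model run through
`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recovers, among others:

```
curiosity_to_path_re   0.0032
interest_to_head_re    0.0053
residual_correlation   0.31    (truth 0.34)
mediation_indirect     0.0019  (truth 0.0039 * 0.80 = 0.0031)
null_hpdi_coverage     0.95    (nominal 0.93)
```

each within two posterior SDs of its generating value for that realisation.

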