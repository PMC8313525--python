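# mobipred

Movement-predictability analysis for timestamped point trajectories.

How predictable is an individual's movement? The answer depends not only on
the person but — strongly and nonlinearly — on how the raw trajectory is
turned into a symbolic sequence: the spatial unit used to define "a place"
(grid cell size, clustering radius), the temporal unit used to sample it
(time-bin width), and whether self-transitions are kept. `mobipred`
implements the full analysis chain so these choices can be swept
systematically, and ships a synthetic trajectory generator with known ground
truth so every stage is testable without access to any proprietary location
dataset. It is aimed at researchers in mobility informatics, movement
ecology and epidemiological mobility modelling.

## The pipeline

1. **Stay-point detection** — scan the trajectory accumulating consecutive
   points within distance δ (default 300 m) of the run's first point; emit a
   dwell episode when the run lasts longer than τ (default 10 min).
2. **Stay-region aggregation** — map stay-points to symbols via a regular
   grid of spacing *G*, or DBSCAN with radius ε and minimum cluster size 1
   (equivalently: connected components of the ε-graph).
3. **Sequence construction** — *next time-bin* sequences (dominant region
   per interval Δt, nulls for empty bins, majority-time rule with
   frequency tie-break) or *next place* sequences (visit order with
   consecutive repeats collapsed).
4. **Entropy** — random entropy S_rand = log₂L; uncorrelated entropy
   S_unc = −Σₖ pₖ log₂ pₖ; actual entropy rate S_est estimated with the
   Lempel-Ziv match-length estimator S_est = (⟨Λⱼ⟩)⁻¹ log₂ n.
5. **Predictability** — solve Fano's inequality
   E = −Π log₂Π − (1−Π) log₂(1−Π) + (1−Π) log₂(L−1)
   for the upper bound Π ∈ [1/L, 1] at each entropy (Π_rand, Π_unc, Π_max).
6. **Missing-data correction** — three estimators of the actual entropy for
   sequences with a fraction q of empty bins (Ĥ_shuff, Ĥ_unc, Ĥ_Δe), plus
   the degradation protocol that benchmarks them on complete sequences.
7. **Experiment harness** — spatial and temporal scale sweeps over synthetic
   populations with median/IQR summaries, and a `mobipred` CLI
   (`simulate`, `staypoints`, `regions`, `sequences`, `entropy`,
   `sweep-spatial`, `sweep-temporal`, `eval-missing`).

## Worked example

```python
import mobipred as mp

# simulate one user: 28 days over 6 anchor locations, 60 s sampling
cfg = mp.random_config(seed=42, n_anchors=6)
traj, truth = mp.generate_trajectory(cfg, user_id="u042")
print(f"trajectory: {len(traj)} points, hour-level q = {mp.hour_level_q(traj):.3f}")

sps = mp.detect_staypoints(traj, delta=300.0, tau=600.0)
agg = mp.dbscan_aggregate(sps, eps=100.0)
print(f"{len(sps)} stay-points -> {agg.n_regions} stay-regions")

visits = mp.visits_from_assignment(sps, agg)
tb = mp.build_time_bin_sequence(visits, delta_t=3600.0)
ent, pred = mp.predictability_profile(tb)
print(f"time-bin sequence: n = {ent.n}, L = {ent.L}, "
      f"S_rand = {ent.s_rand:.2f}, S_unc = {ent.s_unc:.2f}, S_est = {ent.s_est:.2f} bits")
print(f"predictability: Pi_rand = {pred.pi_rand:.3f}, "
      f"Pi_unc = {pred.pi_unc:.3f}, Pi_max = {pred.pi_max:.3f}")

np_seq = mp.build_next_place_sequence(visits)
_, pred_np = mp.predictability_profile(np_seq)
print(f"next place sequence: length {len(np_seq)}, Pi_max = {pred_np.pi_max:.3f}")
```

Output:

```
trajectory: 38700 points, hour-level q = 0.040
191 stay-points -> 6 stay-regions
time-bin sequence: n = 665, L = 6, S_rand = 2.58, S_unc = 1.92, S_est = 1.17 bits
predictability: Pi_rand = 0.167, Pi_unc = 0.593, Pi_max = 0.804
next place sequence: length 186, Pi_max = 0.513
```

Reading this: the user visits L = 6 distinct stay-regions. Knowing nothing
but L, a random guess succeeds 1/6 of the time (Π_rand = 0.167); knowing
visit frequencies raises the ceiling to 0.593; exploiting the full temporal
order of the hourly sequence raises it to 0.804 — about 80% of hourly
locations are predictable in principle. The transition-only view of the same
month is much harder: once self-transitions are removed, the ceiling drops
to 0.513. That gap, and how it moves with the spatial and temporal units,
is what the sweep harness quantifies.

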