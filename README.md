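# tetraschool

An agent-based model of collective swimming in the rummy-nose tetra
(*Hemigrammus rhodostomus*), a species that swims in discrete
burst-and-coast "kicks".  Each fish updates its heading only at kick
onsets, by summing empirically parameterized pairwise attraction and
alignment responses over its *k* most influential neighbors plus Gaussian
noise, and then glides along a straight line:

    δφ_i = Σ_{j ∈ top-k} [ F_Att(d_ij) O_Att(ψ_ij) E_Att(φ_ij)
                         + F_Ali(d_ij) E_Ali(ψ_ij) O_Ali(φ_ij) ] + γ_R g_i

where d is the inter-fish distance, ψ the viewing angle and φ the relative
heading, and a neighbor's **influence** is |δφ_ij|.  The package is for
researchers in collective animal behavior who want to simulate this model
at scale, compute the standard order parameters — dispersion *D* (RMS
distance to the barycenter), polarization *P*, milling index *M* — and map
the schooling / milling / swarming / dispersion phase diagram over the
interaction strengths (γ_Att, γ_Ali), interaction range, noise, group
size, and attention strategy (k = 1 or 2).

The simulator is event-driven and asynchronous (kicks of different fish
interleave in time), deterministic given a seed, and compiled with numba;
a 100-fish, 1000-kick-per-fish run takes on the order of a second.

## Worked example

```python
import tetraschool as ts

params = ts.InteractionParams(gamma_att=0.04, gamma_ali=0.2,
                              l_att=0.28, l_ali=0.28, k=1)
config = ts.SimulationConfig(n_fish=100, params=params, gamma_r=0.2,
                             n_kicks_per_fish=1000, seed=7)
record = ts.run(config)
series = ts.observable_series(record)
post = record.times >= 50  # discard the first 100 kicks (50 s)
P = series.polarization[post].mean()
M = series.milling[post].mean()
D = series.dispersion[post].mean()
print(f"P={P:.2f}  M={M:.2f}  D={D:.2f} m")
print(ts.classify_phase(P, M, D))
```

prints (exactly, for this seed):

```
P=0.85  M=0.12  D=0.18 m
PhaseLabel.SCHOOLING
```

i.e. at this phase point the school is cohesive (*D* well below 5 m),
highly polarized and barely rotating — a schooling state.  Lowering the
alignment strength to `gamma_ali=0.05` at `gamma_att=0.05` instead yields
a vortex (*P* ≈ 0.15, *M* ≈ 0.7, Milling).

The same machinery is exposed on the command line:

```bash
tetraschool simulate --seed 7 --kicks 1000 --out traj.csv --observables obs.csv
tetraschool sweep --gamma-att 0.02 0.08 0.01 --gamma-ali 0.05 0.4 0.05 \
                  --replicates 5 --out grid.tsv
tetraschool diagnose --seed 7 --kicks 1000 --out diag.csv
```

`sweep` writes one phase-labelled row per (γ_Att, γ_Ali) cell; `diagnose`
writes per-second interaction-topology series (distinct most-influential
and nearest-neighbor counts, mean nearest-neighbor distance, 3-group
count).

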