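# blockspin

Community detection in block spin Ising (multi-group Curie-Weiss) models.

A population of `N` individuals — voters answering binary questions, or
specimens scored for a binary trait — is partitioned into `M` latent
groups. Each observation is a configuration `x ∈ {−1,+1}^N` drawn from the
Gibbs measure

```
P(x) = Z⁻¹ exp(−H(x)),   H(x) = −½ Σ_{l,m} J_lm s_l s_m / √(N_l N_m),
```

where `s_l` is the sum of the spins in group `l` and `J` is a symmetric
positive-definite `M×M` coupling matrix (for `M = 1` this is the classical
Curie-Weiss model with `β = J₁₁`). Within-group couplings make members of
the same group agree more often than strangers; the package answers the
inverse question: **given `n` independent observations of the whole
population, which individuals belong together?**

The only statistic used is the matrix of empirical pair correlations
`ȳ_ij = (1/n) Σ_t x_i(t) x_j(t)`. Asymptotic theory pins each group pair's
correlation to a known level:

* **high temperature** (`I − J ≻ 0`): with `H = J⁻¹ − I`,
  `E(X_i X_j) ≈ H⁻¹_{lm} / (√(α_l α_m) N)` for `i` in group `l`, `j` in
  group `m`, where `α_l = N_l/N`;
* **low temperature** (non-critical): `E(X_i X_j) → ⟨Z_l, Z_m⟩`, where the
  vectors `Z_l` are built from `tanh` of the free-energy minima weighted by
  Hessian determinants.

An iterative window recursion then peels off groups from the highest
correlation level downwards; union of the windows' edge sets yields the
partition. The failure probability is bounded by an explicit exponential
(`e(n) = N²(n+1)² exp(−(1/8)(sep/8N or sep/8)² n)`), which also inverts
into a sufficient sample size.

## What's in the box

| module | contents |
| --- | --- |
| `blockspin.model` | model construction and validation, Hamiltonian, exact log-probabilities, regime classification |
| `blockspin.sampler` | exact i.i.d. sampling through the group-sum sufficient statistic (populations in the thousands for small `M`); heat-bath Gibbs fallback |
| `blockspin.landscape` | free energy `F`, its minima and Hessians, asymptotic correlation levels, separation constants `δ`/`γ`, failure bounds, minimal `n` |
| `blockspin.detect` | window recursion, class labelling, model-free banding mode; sklearn-style `CommunityDetector` / `AgnosticCommunityDetector` |
| `blockspin.oracle` | brute-force and de Finetti-quadrature cross-checks, relative entropy, Sanov bound, batch recovery experiments |
| `blockspin.io`, `blockspin.cli` | TSV/CSV samples, JSON/YAML configs, `blockspin` CLI (`simulate`, `theory`, `detect`, `validate`) |

## Worked example

The three-party questionnaire model: an extremist party (strong internal
cohesion, antagonistic to the mainstream), a moderate party, and the
disengaged remainder.

```python
import numpy as np
import blockspin as bs

m = bs.fixtures.three_party_model((2, 2, 2))
th = bs.pair_limit_high(m)
print("regime:", m.regime().tag)
print(np.round(th.H_inv, 4))
sep = bs.separation_from_matrix(th.H_inv, regime="high")
print(f"eta = {sep.eta:.4f}, xi = {sep.xi:.4f}, delta = {sep.value:.4f}")
```

prints

```
regime: high
[[ 5.5517 -2.7586  2.069 ]
 [-2.7586  2.7931 -0.3448]
 [ 2.069  -0.3448  1.7586]]
eta = 3.1379, xi = 1.0345, delta = 1.0345
```

The diagonal of `H⁻¹` orders the groups by cohesion (the extremist group's
`5.5517` tops the list, so its members' correlations cluster highest), and
`δ = 1.0345` is the worst-case gap separating the correlation levels — it
sets the detection window width and the sample-complexity bound.

End-to-end detection on a low-temperature model (two antagonistic cohesive
groups, `J = [[1.5, −0.1], [−0.1, 1.5]]`, ten members each):

```python
low = bs.fixtures.polarised_pair_model()
L = bs.find_minima(low)
print("minima:", [np.round(mm.z, 5).tolist() for mm in L.minima])
print("gram:", np.round(L.gram, 5).tolist())
gamma = bs.separation_constants(L)
n = bs.min_observations("low", low.N, gamma, eps=0.2)
print(f"gamma = {gamma.value:.5f}, n* = {n}")

sample = bs.draw_sample(low, n, seed=1)
det = bs.CommunityDetector(model=low).fit(sample.data)
print(det.result_.status, det.labels_)
```

prints

```
minima: [[-1.00765, 1.00765], [1.00765, -1.00765]]
gram: [[0.79325, -0.79325], [-0.79325, 0.79325]]
gamma = 1.58649, n* = 5013
success [0 0 0 0 0 0 0 0 0 0 1 1 1 1 1 1 1 1 1 1]
```

The free energy has two anti-aligned minima; within-group correlations
concentrate near `+0.793`, cross-group near `−0.793`, and `n* = 5013`
observations suffice for the failure bound to drop below 0.2 (in practice
recovery succeeds far earlier). The recovered labels match the planted
blocks exactly.

The same pipeline from the shell:

```bash
blockspin theory   --config model.yaml --eps 0.2
blockspin simulate --config model.yaml --n 5013 --seed 1 --out sample.tsv
blockspin detect   --sample sample.tsv --config model.yaml --out partition.tsv
blockspin detect   --sample sample.tsv --agnostic --out partition2.tsv   # model-free
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the package alone, the separation constants `η` and `ξ`
of the worked example (Definition-style minima over group pairs of the
`H⁻¹` diagonals and off-diagonals) and writes them as JSON.
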