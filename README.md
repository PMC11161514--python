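# physnet

Growth, scaling theory and Laplacian spectra of **physical networks** —
networks whose nodes are extended, volume-excluding objects living on a
lattice substrate — represented as networks-of-networks.

## What it does

- **Growth model** (`physnet.growth`): grows a physical network on a
  `d`-dimensional periodic cubic lattice. A first node is grown freely to a
  target volume; each later node is seeded at a random unoccupied site and
  grows — by a loop-erased random walk, or a digitized straight ray — until
  it hits the existing network, forming one bond and one combinatorial
  link. Run to saturation the walk process produces a uniform spanning tree
  of the torus partitioned into node trajectories.
- **Theory** (`physnet.theory`): closed-form scaling predictions —
  intersection probability of two trajectories, next-node volume, total
  volume `V_t ~ t^(1-d_f/d)`, expected degrees `k_t ∝ v_t`, and the degree
  exponent `γ = 1 + d/d_f` (γ = 3 in the mean-field regime `d_f ≤ d/2`).
- **Observables** (`physnet.observables`): CCDFs, discrete-MLE power-law
  tail fits with KS-selected cutoff, trajectory fractal-dimension
  estimation, volume-growth exponents, degree–volume relations, and
  saturation scaling.
- **Spectral** (`physnet.spectral`): the site-level layout Laplacian
  `Q_P(w)` (intra-node weight 1, inter-node bond weight `w`), the weighted
  combinatorial Laplacian `Q_G`, and the volume-normalized physical
  Laplacian `Q_phys = V^{-1/2} Q_G V^{-1/2}`; first-order perturbation
  checks that the `N` slow eigenvalues of `Q_P(w)/w` converge to
  `eig(Q_phys)`, plus eigenvector localization and volume-shuffled null
  models.
- **Real networks** (`physnet.realnet`): load any weighted undirected edge
  list (TSV: `node_i  node_j  multiplicity`) plus node volumes (TSV:
  `node_id  volume`), normalize mean volume to 1, fit power laws with
  exponential cutoff, and compare combinatorial vs physical spectra —
  including the identity of the leading-eigenvector localization center
  (`argmax k_i/v_i` for the physical Laplacian). A fixture generator
  provides heavy-tailed synthetic networks with tunable degree–volume
  correlation.

## CLI

```sh
physnet grow -d 2 -L 100 --seed 1 --out runs/demo      # grow to saturation
physnet theory -d 2 --d-f 1.25 -L 100                  # prediction table
physnet figure2 -d 2 -L 100 --seed 1 --out runs/fig2   # scaling tables
physnet spectrum -d 2 -L 10 --seed 1 --out runs/spec   # w-sweep + spectra
physnet fixture -n 1000 --mode linear --out runs/fix   # synthetic network
physnet realnet runs/fix/edges.tsv runs/fix/volumes.tsv --out runs/report
```

All outputs are TSV/CSV/JSON; every run records its seed and config hash
(`run_meta.json`), and identical configs reproduce outputs bit for bit.

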