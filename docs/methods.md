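# Methods

## Model

`tcsdca` models the joint distribution of interacting sensor-kinase (SK) /
response-regulator (RR) sequence pairs as a pairwise maximum-entropy
(Potts) model over the concatenated alignment. With q = 21 states (20
amino acids in alphabetical order, gap last),

    P(A_1 … A_L) = Z^{-1} exp( Σ_{i<j} e_ij(A_i, A_j) + Σ_i h_i(A_i) ),

the couplings e_ij and fields h_i are chosen so the model's one- and
two-site marginals agree with reweighted, pseudocounted empirical
frequencies. The model assumes that observed inter-protein covariation is
generated by a time-invariant set of contact preferences shared across the
family, and that sequences are exchangeable once phylogenetic redundancy
is down-weighted. It does not model insertions (only HMM match columns),
epistasis beyond pairs, or lineage-specific effects.

### Frequencies

Row a of the joint MSA receives multiplicity m_a = #{rows with strictly
more than `identity_threshold` of identical aligned positions (gap–gap
counts as identical), itself included}; its weight is 1/m_a and
M_eff = Σ 1/m_a. Frequencies add a uniform pseudocount λ:

    f_i(A)    = (λ/q  + Σ_a δ(A, x_i^a)/m_a) / (λ + M_eff)
    f_ij(A,B) = (λ/q² + Σ_a δ(A, x_i^a) δ(B, x_j^a)/m_a) / (λ + M_eff)

These satisfy normalization, marginal consistency and index symmetry
exactly (tested at 1e-12). The self-pair convention is
f_ii(A,B) = f_i(A) δ(A,B).

### Inference backends

Columns entering the fit are selected greedily from the strongest
inter-protein mutual-information pairs, up to `n_columns` (default 70),
with lexicographic tie-breaks.

* **plm** (default): symmetric pseudo-likelihood maximization, L-BFGS on
  the weighted mean per-sequence objective with L2 penalties
  (`reg_coupling = reg_field = 0.01`). One-hot algebra reduces each
  objective/gradient evaluation to two dense matrix products, so a
  2000-sequence, 45-column fit converges in seconds.
* **mf**: naive mean-field — couplings from the negative inverse of the
  connected-correlation matrix on the (q−1)-state reduced alphabet, fields
  from the mean-field self-consistency relation. Orders of magnitude
  faster, less accurate; used for large scans.
* **exact**: convex dual minimization (log Z minus the empirical moments)
  on the fully enumerated state space; only feasible for q^n up to a few
  hundred thousand and used as the oracle backend in tests, where its
  marginals match the targets to 1e-8.

All backends report their parameters in the **zero-sum gauge**
(Σ_A e_ij(A,B) = Σ_B e_ij(A,B) = 0, Σ_A h_i(A) = 0), which makes coupling
signs directly readable as favorable/unfavorable and is recorded in every
serialized model. All downstream quantities (direct distributions, direct
information, interaction scores) are gauge-invariant; tests verify score
invariance under random gauge reparameterizations at 1e-10.

### Direct distributions and score

For a retained pair, P^dir_ij(A,B) ∝ exp(e_ij(A,B)) with row/column
scalings fitted by iterative proportional fitting until both marginals
match f_i, f_j (max-abs residual < 1e-10, cap 10⁴ sweeps; non-convergence
raises). *Direct information* — the mutual information of P^dir — is the
default coupling-strength ranking; the Frobenius norm of the zero-sum
block is available as an alternative.

The interaction score of a candidate (sk, rr) pair is the log-likelihood
ratio against the factorized null (independent per-column statistics),
restricted to inter-protein pairs among the selected columns:

    S = Σ_{i∈SK, j∈RR} ln [ P^dir_ij(A_i, B_j) / (f_i(A_i) f_j(B_j)) ].

All retained inter-protein pairs are summed, not only the top-ranked ones:
the top-k set matters only for the physical-interpretation analysis. A gap
at a scored position contributes its actual table entry (the gap is a
bona fide 21st state); a `skip` policy that omits gapped pairs is
available by flag. Scores are in natural-log units, and per-pair
contributions are returned so individual interface contacts can be
inspected.

Two baselines are implemented for benchmarking: the same sum with raw
pair-frequency ratios ln[f_ij/(f_i f_j)] (local covariance, which
over-counts indirect couplings), and a k-nearest-neighbor score (default
k = 2): mean RR %identity to the RRs of the k training pairs nearest by SK
identity, symmetrized across the two directions, in percent.

## Interaction modes

The averaged coupling matrix of the top-k (default 10) strongest
inter-protein pairs is projected onto feature vectors: electrostatic
(+1 on H/K/R, −1 on D/E, prefactor −1 because opposite charges attract),
hydrophilic (1 on D,E,H,K,N,Q,R,S,T) and hydrophobic (1 on
A,C,F,I,L,M,V,W,Y), both prefactor +1; the hydrophilic/hydrophobic split
roughly follows the Wimley–White interface scale, and custom vectors are
accepted. The overlap q = prefactor · ξᵀ Ē ξ is tested against a null of
uniformly random permutations of the 20 amino-acid labels (gap fixed).
The empirical p-value is add-one smoothed — 10⁶ permutations cannot
resolve tails below 10⁻⁶ — so the Gaussian tail at the null Z-score is
reported alongside it; extreme tail claims rest on the Gaussian value.

## Genome extraction rules

Gene classification from domain-hit tables: an SK call needs an accepted
sensor-kinase domain (E ≤ 10, best E-value selects the family, ties broken
by the canonical family order) plus a C-terminal ATPase support hit
(E ≤ 0.01); an RR call needs a receiver domain at E ≤ 0.01; both ⇒ hybrid,
excluded from modeling. Operons are maximal same-strand runs on one
replicon with intergenic distance ≤ 200 bp (inclusive; overlapping genes
count as distance 0). An operon yields a cognate pair iff it has exactly
one SK (HisKA class by default) and one RR and no hybrid; operons with
multiple SKs or RRs are excluded entirely. Remaining SKs are orphans;
remaining RRs are orphans unless co-operonic with an alternative kinase
class (HisKA_2, HisKA_3, HWE_HK) or an Hpt phosphotransfer gene. Gene
coordinates are 0-based half-open internally; table files use 1-based
inclusive coordinates and say so.

## Synthetic data

The default planted benchmark uses L_SK = 20 and L_RR = 25 columns —
deliberately smaller than the real SK/RR domain lengths (87/117) so
end-to-end fits run in seconds to minutes — with q = 21 and six disjoint
inter-protein column pairs carrying a charge-complementarity coupling
block (opposite charges +1, like charges −1 on the 5 charged residues,
double-centered to zero-sum; magnitude ~1). Fields give charged residues
a +1.5 bonus at planted columns (so interacting states are actually
populated), every column receives mild N(0, 0.3) random fields for
realistic composition, and gaps are suppressed by −2. Sampling uses one
independent Gibbs chain per output row (heat-bath single-site updates,
1000 burn-in sweeps over the coupled sites; independent sites are sampled
exactly); the sampler is validated against exact two-site enumeration of
planted blocks. Pseudo-genomes group 10 consecutive pairs; within-genome
non-cognates are random cyclic derangements, so a shuffle never
reproduces a cognate pair.

What the generator does *not* emulate: realistic phylogenies (redundancy
is modeled as near-duplicate rows at a chosen mutation rate, not a tree),
alignment errors, gap structure of real domains, composition biases
beyond the random fields, and multi-domain architecture. Passing tests
therefore demonstrate correctness and calibration of the machinery under
the model's own assumptions, not performance on biological corpora.

## Numerical choices and defaults

| parameter | default | rationale |
|---|---|---|
| identity_threshold | 0.80 (strict >) | redundancy cutoff; results robust in 0.7–0.9 |
| pseudocount λ | M_eff | equal weight to data and uniform prior; keeps all frequencies positive |
| n_columns | 70 | bounds the fit to the most-correlated positions |
| top_k | 10 | averaging window for interaction-mode analysis |
| plm regularization | 0.01 | L2 per parameter on the mean per-sequence objective |
| IPF tolerance | 1e-10, cap 10⁴ sweeps | marginal-matching contract |
| score thresholds | 20 / 30 / 60 | crosstalk reporting bands (natural-log units) |
| n_perm | 10⁶ | permutation-null resolution |

Determinism: all generators are pure functions of (parameters, seed); tie
breaks in column selection, coupling ranking and orphan ranking are
lexicographic; reruns of the pipeline with one configuration are
bit-identical.

## Problem sizes used in validation

The shipped validation study fits the default planted model at n = 2000
training pairs (the main study), n = 10⁴ for the coupling-recovery
experiment, and n ∈ {200, 600, 1800} × 5 seeds for the training-size
curve. At n = 2000 the fitted/planted coupling Pearson correlation over
the planted blocks is ≈ 0.86 in zero-sum gauge (≈ 0.96 over the
strongly-coupled charged entries) and reaches ≈ 0.94 at n = 10⁴: entries
pairing a charged with a neutral residue have planted magnitude ~0.05 and
only a handful of expected observations per cell at n = 2000, so their
estimates are sampling-noise limited. Pair recovery is easier than
coupling-value recovery: all six planted pairs occupy the top six direct-
information ranks from n ≈ 200 on.

## Known limitations

* The fitted average coupling matrix is only asymptotically symmetric for
  symmetric planted rules; its antisymmetric part is sampling noise
  decaying like n^{-1/2} (≈ 0.3 relative at n = 2000).
* Mean-field couplings are biased at strong coupling and small samples;
  use `plm` when accuracy matters.
* The score is a log-likelihood ratio, not a calibrated interaction
  probability; thresholds are corpus-dependent conventions.
* The kNN baseline is quadratic in corpus size and intended for
  benchmarking, not production scanning.
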