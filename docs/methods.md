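# Methods

This note documents the model, the numerical and design choices behind the
implementation, what the synthetic studies do and do not show, and known
limitations.

## Rate-based model

A class is scored by a pair of dendritic trees (excitatory PDT, inhibitory
NDT). Connectivity is an m×d matrix of non-negative integer multiplicities
with every row summing to exactly k; learning preserves this row-sum
invariant at every step, so the synapse budget per dendrite is hard-wired.
Multiple contacts from one afferent onto one dendrite are allowed (integer
weights > 1 arise naturally and are retained in weight-map rendering).

The branch nonlinearity is the rectified quadratic
b(z) = (z − z_leak)² · [z > z_leak]. Two conventions are fixed here:

* **The boundary is inactive**: b = 0 at z = z_leak exactly (the gate opens
  only for strictly positive drive).
* **z_leak in the rate path**: the leak term is part of the dendritic
  nonlinearity, so it is applied in the rate model too, not only in the
  spiking path. It is computed once per branch as the mean activation of the
  branch's *initial random* connectivity over the training set and then
  frozen — it models a balancing inhibitory pool calibrated to the initial
  wiring, and keeping it fixed makes the learning signal stationary.

The WTA breaks ties deterministically toward the lowest class index — this
shows up in degenerate cases (all-zero inputs) and makes runs reproducible.
At test time decisions are always the hard argmax; the soft margin output
g_margin (linear ramp of half-width δ, g_margin(0) = 1/2) exists only inside
training. With δ = 0 the ramp degenerates to the hard threshold with the
midpoint convention g(0) = 1/2, so an exact score tie counts as an error —
a tie is not a correct classification.

## Structural learning

One iteration makes one replacement attempt per dendritic tree (classes in
fixed ascending order, PDT before NDT). This scheduling is a determinism
choice; the attempts are otherwise independent. Per attempt:

1. the correlation map c_ij = ⟨x_i b_j sgn(y_d − y)⟩ is computed for the
   tree (sign flipped for the NDT). Patterns whose soft output already
   matches the teacher contribute nothing; silent (unconnected) entries of
   the map score hypothetical synapses, which by construction do not
   contribute to b_j;
2. n_T active synapse slots are sampled without replacement (counting
   multiplicity); the lowest-correlation one is the replacement target. If a
   tree has fewer than n_T synapses — small initial trees during adaptive
   growth — the candidate set is clamped to all of them;
3. n_R candidate afferents are drawn without replacement for the target
   dendrite; the highest-correlation candidate replaces the target (the same
   afferent may be re-drawn across attempts). The swap is kept iff the
   margin training error did not increase.

**Local minima.** The stagnation counter counts consecutive attempts without
a *strict* error decrease (rejected swaps and accepted-but-equal swaps
alike) and is reset by any strict decrease. When it reaches n_ch the current
wiring is checkpointed if it is the best seen, a local minimum is recorded,
and the last rejected replacement is forced through to escape. Counting
equal-error accepts as stagnation is essential: otherwise a learner cycling
through equal-error rewirings would never accumulate minima and never
terminate. Termination is guaranteed — between any two minima the error can
strictly decrease at most P times, so the n_min budget is always reached if
memorization is not.

**Margins.** Training runs first with the hard threshold; per-class margins
are then set to the largest score deficit among that class's validation
misclassifications (0 for clean classes) and training continues under the
soft objective. Two local minima are considered "the same" when their error
values are equal; five consecutive identical minima decay all margins to
80% of their value. The error-equality criterion is the simplest observable
identity for minima; wiring-level identity would almost never fire because
forced escapes keep perturbing the matrix.

## Adaptive growth

Per-class errors (fraction of that class's patterns not yet satisfied) drive
growth. A class stalls when its error has not reached a new low for n_ch
iterations; a stalled class receives one fresh dendrite on *both* its trees
(k random contacts appended as a new row; the new branch's leak level is the
mean activation of its own initial row) provided its error is currently the
highest of all classes (scheme 2) or it is among the 5 worst (scheme 1).
Two guards matter in practice:

* a class at zero error neither stalls nor grows — it is done, not stuck;
* the highest-error guard keeps growth aligned with difficulty. Without it,
  classes stuck at a handful of residual errors stall first (they rarely
  find new lows) while the genuinely hard class keeps improving in small
  steps and never stalls, so easy classes would out-grow hard ones.

Growth stops when the hard-WTA validation error (held-out 20% split) has
increased at each of the last three additions; the whole run then stops and
the connections are frozen as they stand. Runs that instead end by
memorization or the minima budget return the best checkpoint.

## Capacity and optimal topology

C_NL = 2 log₂ C(f+m−1, m) with f = C(k+d−1, k) counts distinguishable
connection configurations. The default evaluation is in the log domain via
log-gamma: f is astronomically large already at MNIST scale (f ≈ 10⁹⁵ for
k=64, d=784), so C(f+m−1, m) is accumulated as Σ_t log(f+t) with
log1p-corrected terms. An exact big-integer path (`capacity_bits_exact`)
is kept for cross-checking on small arguments; the two agree to 1e-9
relative for all m, k, d ≤ 8. `optimal_topology` scans only integer divisor
pairs of s (synapse counts are integers even though the capacity curve is
smooth in m) and resolves ties toward larger m, consistent with the flat-
tree optimum.

## Spiking path

Spikes evoke the causal double-exponential PSC
K(t) = I₀(e^(−t/τ_f) − e^(−t/τ_r)); branch activations z_j(t) are the
connection-weighted sums of per-afferent PSC traces. The time-resolved leak
is the stored rate-model z_leak scaled by the reference single-spike kernel
K(t − T_syn): for the noiseless single-spike code used to calibrate the rate
model this *is* the mean branch activation trace, and it is kept as the
stored calibration under noisy inputs too. A consequence worth knowing: for
noiseless single-spike inputs the class input current factorizes as
I_in(t) = K(t−T_syn)² · o^μ(x), so the spiking WTA reproduces the rate WTA
up to spike-count quantization — this is why the rate/spike agreement is
~99% rather than exactly 100%.

LIF integration is fixed-step forward Euler (dt = 0.1 ms, thresholds handled
at step boundaries) of τ_V V̇ = (u − V) + I_in with a slow hyperpolarization
u (τ_u = 200 ms) reset to V_reset on each output spike. Parameter defaults:
τ_V = 5 ms, V_thr = 0.1 mV, T = 200 ms, T_syn = 100 ms. The PSC constants
are this package's choices (I₀ = 1, τ_f = 10 ms, τ_r = 2 ms — fall/rise on
the scale of the membrane dynamics), as is V_reset = −V_thr = −0.1 mV
(only its negativity is constrained by the model). Spike counts in the
classification regime are O(10); halving dt moves them by at most one.

## AER memory model

The two-tier layout stores, per afferent, the cumulative synapse count
(pointer array, d entries of ⌈log₂(H·k)⌉ bits, with a₀ = 0 implicit so
exactly d entries are stored) and a flat dendrite-address array (H·k entries
of ⌈log₂ H⌉ bits, sized at full capacity regardless of fill). Routing an
event reads two consecutive pointers and fans out to n_i = a_{i+1} − a_i
consecutive destinations; encode/decode is lossless on connection
*multisets*. NOB_conv = b·H·d + b·H·C prices the dense b-bit crossbar
(area uses the b·H·d crossbar approximation, valid for C ≪ d);
NOB_prop = d·⌈log₂(H·k)⌉ + H·k·⌈log₂ H⌉ prices the two-tier layout. Both
are exact integer formulas; the area report multiplies by a per-bit SRAM
area (0.15 µm²/bit default).

## Synthetic studies: what they show

The generator draws random binary prototypes per class and emits noisy
copies by independent bit flips. Default benchmark: N_C = 4, d = 64,
2 prototypes/class, 5% flip noise, 200 train + 200 test patterns — sized so
a full train/test cycle takes well under a second and a 20-member ensemble
study a few seconds. The growth benchmark makes class 0 a union of 24
prototypes at 15% noise (others single prototypes, 100 patterns/class) and
starts from m = 2, k = 5 with n_ch = 25: the hard class's structure then
genuinely exceeds the initial tree's capacity, so growth is exercised rather
than bypassed by early memorization. The studies use n_min = 150, n_T =
n_R = 25 unless a tree is too small (see clamping above).

What passing these studies shows: the learning rule memorizes by rewiring
under its stated termination rules; ensembles of differently-initialized
members do not generalize worse than their average member; growth allocates
dendrites by difficulty; the spiking network reproduces rate decisions.
What they do not show: absolute accuracy on natural image data (real digit
benchmarks have correlated pixels, unbalanced difficulty across ten classes,
and d = 784), robustness at MNIST scale, or wall-clock behaviour of
hour-long training runs. Single small networks here lose more accuracy
under 10–20 ms spike jitter (roughly 10–20 percentage points on the
benchmark) than large ensembles on high-dimensional inputs would: with only
~50 active afferents per pattern and a 10 ms PSC fall time there is little
averaging over timing noise.

## Degenerate inputs and numerical conventions

Empty pattern sets, zero-budget training (n_min = 0 returns the initial
model), all-zero patterns (classify to the tie-break class), score ties
(errors during training, lowest index at test), patch ties in event-frame
cropping (top-left-most), and capacity ties (larger m) are all defined
behaviours with tests. Model files are JSON (small integer matrices);
pattern sets are compressed `.npz` archives; event streams and growth logs
are CSV.

## Limitations

* Learning is rate-based; spike-domain usage is evaluation only (no
  spike-time-based learning rule is provided).
* Dendrite growth is append-only; there is no pruning.
* The LIF path simulates one neuron pair per class independently; no shared
  WTA circuit dynamics or lateral inhibition are modelled.
* The AER model counts memory bits and area only; routing latency and
  multi-core partitioning overheads are out of scope.
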