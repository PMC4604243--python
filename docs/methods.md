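# Model and methods

## The model

`columnet` simulates a patch of layer 2/3 cortex organized into a square
grid of hypercolumns (default 6 x 6, 500 um apart), each containing six
minicolumns.  A minicolumn holds 30 pyramidal cells (PC), 3 Martinotti cells
(MC) and 3 VIP cells; each hypercolumn adds 8 basket cells (BC) that inhibit
all of its minicolumns (winner-take-all inhibition).  Same-index minicolumns
across hypercolumns encode the same stimulus feature ("pattern") and are
linked by long-range projections: every PC sends one terminal field to a
uniformly chosen same-pattern minicolumn in another hypercolumn, contacting
4 PC and 1 MC there.  Long-range recruitment of MC supplies
minicolumn-specific disynaptic inhibition; a VIP -> MC pathway disinhibits
PC when VIP cells are driven.

### Neurons

Single-compartment Hodgkin-Huxley cells with transient Na, delayed-rectifier
K and a slow M-type K current (spike-frequency adaptation), using
Traub-Miles-style kinetics shifted by a threshold parameter `V_T`.
Channel densities, reversal potentials and soma diameters are per-type
constants (PC: 96 um; BC/MC/VIP: 67 um, higher leak and K densities,
all adapting).  VIP cells reuse the MC parameter column, as no separate
measurements are available.

Two quantities the parameter table does not determine had to be set:

* **Soma length.**  The soma is a cylinder of diameter d and unspecified
  length L; the lateral area pi*d*L converts channel densities to absolute
  conductances and fixes the input resistance.  Because the drive constants
  (background mean 0.000121 uS, stimulus levels g1..g5 = 0.0028, 0.0024,
  0.0020, 0.0022, 0.0025 uS) are absolute conductances, the area decides how
  strong the stated drives are.  With L = d a PC has R_in ~ 34 MOhm and the
  default stimulus is several-fold subthreshold, leaving the network silent
  at every stated drive level.  The package sets L = 0.30 d, giving
  R_in ~ 115 MOhm (PC) and ~ 150 MOhm (interneurons) - physiological for
  layer 2/3 cells - and placing the default stimulus level g2 just at PC
  threshold, so that stimulation produces sustained firing in the tens of Hz
  as the network is described to do.  `soma_length` is configurable.

* **V_T.**  The kinetic threshold shift is not tabulated.  PC use -55 mV.
  Interneurons are set more excitable - BC at -58 mV, MC/VIP at -60 mV -
  reflecting the lower spike thresholds of fast-spiking and
  low-threshold-spiking (Martinotti) interneurons.  Without this ordering
  the interneurons, which receive no feedforward stimulus and only
  0.1-1.7 mV unitary EPSPs, never leave rest and every
  interneuron-mediated phenomenon is trivially absent.  `tau_max` for the
  M current (also missing from the table) defaults to 1000 ms.

### Synapses

Kinetic receptor models (AMPA/kainate, NMDA, GABA_A): a drive variable x is
incremented per presynaptic spike and decays with tau_x (0.05 ms for
AMPA/GABA_A, 5 ms for NMDA); the open fraction follows
ds/dt = alpha_s x (1-s) - s/tau_s (tau_s = 6 ms, 150 ms for NMDA).  The
NMDA current carries the standard magnesium block
B(V) = 1/(1 + [Mg] exp(-0.062 V)/3.57) with [Mg] = 1 mM (configurable; the
concentration is not stated).

Short-term plasticity follows the resource model: release scale U_eff * R
per spike, R recovering with tau_rec; facilitating synapses make U dynamic
(increment U1 (1-U), decay tau_facil).  Class constants: PC-PC depressing
(U = 0.4, tau_rec = 600 ms); PC-BC depressing (U = 0.5, tau_rec = 600 ms -
the class table labels the row "facilitating" but with tau_facil = 0 and
the text calling PC-BC depressing, the depressing reading is used);
PC-MC facilitating (U1 = 0.05, tau_rec = 20 ms, tau_facil = 1000 ms);
all GABAergic classes depressing (U = 0.25, tau_rec = 500 ms).

**Calibration.**  Peak conductances are not free parameters: for every
(class, receptor) pair, G is set by bisection so that a single presynaptic
spike onto the resting postsynaptic cell produces the tabulated unitary PSP
(PC-PC 1.2/0.6 mV AMPA/NMDA, long-range 0.3/0.15 mV, PC-BC 1.7 mV,
PC-MC 0.1 mV, BC-PC -1.4 mV, MC-PC -0.6 mV, VIP-MC -0.2 mV) to within
0.01 mV.  The first-spike release scale (U or U1) is absorbed into G, so a
facilitating PC-MC synapse starts at 0.1 mV and grows roughly tenfold under
sustained drive (the "burst detector").  NMDA is calibrated with the Mg
block clamped open: a 0.6 mV NMDA component measured at rest would imply an
implausibly large conductance (the block passes only ~4% at -70 mV), so the
printed amplitude is read as the conductance scale of the unblocked
receptor.  The flag `clamp_mg_block=False` restores the
blocked-at-rest convention.

### Connectivity

Bernoulli wiring at the tabulated probabilities: PC-PC 25% within a
minicolumn; PC->MC 30% and MC->PC 80% within a minicolumn; PC->BC and
BC->PC 70% within a hypercolumn; VIP->MC 60% within a minicolumn.  (The
text gives 40% for PC->MC; the parameter table's 30% is used.)  Long-range
wiring is one terminal field per PC as described above.  Conduction delays
are distance over speed with speed drawn per connection from a Gaussian
(mean 0.3 m/s, sd 0.2 x mean, truncated at 5% of the mean), yielding the
right-skewed, gamma-like delay distribution expected from a ratio of
distance to Gaussian speed.

Six wiring variants control the long-range inhibitory relay.  Type 1:
orientation-specific MC (the reference).  Types 2/3: terminals redirected
to the hypercolumn BC pool (unspecific), with depressing (Type 2) or
facilitating (Type 3) terminal dynamics - the source figure distinguishes
the two variants only pictorially, so both BC presets are exposed without
asserting which is which.  Type 4: MC pools merged hypercolumn-wide
(orientation-unspecific MC).  Type 5: no long-range inhibitory terminal.
Type 6 ("orientation-specific BC") keeps the minicolumn-specific relay
wiring of Type 1 but gives the PC->relay synapses depressing BC-type
dynamics; this realizes a minicolumn-tuned, depressing interneuron without
dismantling the hypercolumn WTA circuit.  Weight compensation keeps total
inhibition comparable across variants: inhibitory output classes conserve
(in-degree x weight) per PC, and excitation onto an interneuron pool
conserves the summed product across its local + long-range classes
(e.g. Type 5 scales PC-MC_LO by 19/9 after removing the ~10 long-range
inputs per MC; Type 4 scales MC->PC by 1/6 after pooling).

### Drive

All cells receive a point-conductance background: an Ornstein-Uhlenbeck
excitatory conductance (E = 0 mV) with mean 0.000121 uS and correlation
time 2.7 ms, clipped at zero.  The stationary SD is not stated; it was
calibrated once so that the default network with noise alone fires at the
stated sparse PC background rate (0.5-1 Hz), giving sd = 0.0026 uS for PC.
Because the same conductance fluctuation produces much larger voltage
fluctuations in the smaller interneurons, the SD applied to each type is
scaled by its input conductance and RC filtering so that all types
experience the PC-calibrated voltage fluctuation
(`equalize_fluctuations=False` restores a literal single SD).  The
feedforward stimulus uses the same mechanism: every PC of a driven
minicolumn gets a private process with mean g_i during the stimulus window;
VIP cells of driven minicolumns get mean 0.0018 uS when the
locomotion-like VIP drive is on.

### Integration

Fixed-step integration (default dt = 0.025 ms, 0.05 ms for the reduced
network experiments): exponential-Euler updates for V (against the
instantaneous total conductance) and for all gates (via per-type lookup
tables at 0.05 mV resolution); the synaptic drive x decays exactly and s is
advanced against the within-step average of x, which keeps the update
accurate although tau_x (0.05 ms) is comparable to dt.  Spikes are upward
crossings of 0 mV with a 2 ms lockout; deliveries are queued per connection
with delays rounded up to the dt grid (a perturbation < dt), and the
short-term plasticity recursion runs event-wise at arrival using exact
closed forms.  A halve-step control (`engine.halve_step_check`) compares
population rates at dt and dt/2.  Runs are bit-reproducible given
(network spec, drives, dt, seed); construction, long-range target choice,
delays and dynamical noise use separate seeded streams so that wiring
variants share all common structure.

## Reduced-scale experiments

The experiment runners reproduce the four published protocols on a reduced
3 x 3-hypercolumn grid (2016 cells) with 3 trials, chosen so a full
experiment completes in minutes on one CPU: size-dependent suppression
(3 vs 9 driven same-pattern minicolumns), contextual contrast (full-field
drive, recorded hypercolumn in a homogeneous vs contrasting background),
center-surround delta (2 x 2 center block of one pattern against the
surround pattern, delta = PC rate at a center site minus a surround site)
across Types 1-6 and PC-MC facilitation time constants, and the VIP
disinhibition size series (1-9 driven minicolumns, VIP drive on/off).

## Known limitations

* **Magnitudes of the network phenomena.**  The tabulated inhibitory
  parameters bound the influence of the interneuron pathways tightly.  A
  depressing synapse's steady transmission saturates at ~1/tau_rec full
  PSPs per second (2/s at tau_rec = 500 ms), so a PC receives at most ~5
  effective IPSPs/s from its 2.4 MC inputs regardless of MC rate - a mean
  hyperpolarization well under 0.1 mV.  Direct measurement in the model
  confirms the bound: driving the recorded minicolumn's MC from 32 to
  126 Hz lowers its PC rate by only ~0.3 Hz on a ~21 Hz response.  The
  same arithmetic applies to VIP->MC (-0.2 mV unitary, 1.8 inputs).
  Consequently the suppression, saliency and disinhibition effects this
  implementation produces are differentials of a few tenths of a Hz -
  correct in mechanism and often in direction, but one to two orders of
  magnitude smaller than the published traces, and comparable to
  trial-to-trial and realization noise at desk scale.  Reproducing the
  published magnitudes would require synaptic efficacies well above the
  unitary-PSP reading of the parameter tables.
* The synthetic background emulates stationary in-vivo-like bombardment
  only; no oscillations, no layer-4 circuitry, no dendritic morphology
  (MC normally target distal dendrites - a single compartment cannot
  express that).
* Long-range connectivity is distance-independent, with exactly one
  terminal field per PC.
* Passing the reduced-scale sign checks shows the wiring and plasticity
  machinery behave as designed; it does not certify the full-scale
  dynamics of the original 8064-cell network.
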