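# columnet

A conductance-based spiking model of a layer 2/3 cortical patch, built to
study how long-range recruitment of Martinotti cells produces surround
suppression and center saliency, and how a VIP-cell disinhibitory pathway
removes that suppression.

The network is a grid of hypercolumns (default 6 x 6, 500 um apart), each
with six minicolumns acting as feature detectors.  A minicolumn contains 30
pyramidal cells (PC), 3 Martinotti cells (MC) and 3 VIP cells; 8 basket
cells (BC) per hypercolumn provide shared winner-take-all inhibition.
Cells are single-compartment Hodgkin-Huxley neurons (Na, delayed-rectifier
K, and an adapting M-type K current):

    C_m dV/dt = -G_leak (V - E_leak) - g_Na m^3 h (V - E_Na)
                - g_Kd n^4 (V - E_K) - g_M p (V - E_K) + I_syn

Synapses are kinetic AMPA/NMDA/GABA_A receptors (first-order gating with
the NMDA magnesium block) with Tsodyks-Markram short-term plasticity: a
fraction U_eff * R of the vesicle pool is released per spike, with
depression (R, tau_rec) everywhere and a dynamic, facilitating U on the
PC -> MC pathway (U1 = 0.05, tau_facil = 1 s) that makes MC burst
detectors.  Peak conductances are calibrated so that single-spike PSPs at
rest match the tabulated unitary amplitudes (e.g. PC-PC 1.2 mV, PC-BC
1.7 mV, BC-PC -1.4 mV, MC-PC -0.6 mV, VIP-MC -0.2 mV).  Minicolumns of the
same index in different hypercolumns form a pattern linked by long-range
connections: each PC contacts 4 PC and 1 MC in one randomly chosen
same-pattern minicolumn elsewhere.  Six wiring variants (Type 1..6) move
that interneuron terminal between MC and BC, change its dynamics, and
change the relay's orientation specificity.

See `docs/methods.md` for the full model description, parameter choices and
known limitations.

## Worked example

Build a reduced 3x3-hypercolumn network, drive one pattern at the default
stimulus level, and measure the recorded minicolumn's rates:

```python
import numpy as np
from columnet.network import NetworkSpec, build_network
from columnet.engine import SimConfig, run
from columnet.drive import StimulusField
from columnet.analysis import binned_rate
from columnet.neurons import CellType

net = build_network(NetworkSpec(grid=(3, 3), seed=1))
stim = StimulusField(tuple((h, 0) for h in range(9)),  # whole pattern 0
                     level="g2", onset=200.0, duration=1000.0)
res = run(net, SimConfig(dt=0.05, t_total=1300.0, seed=11), stimulus=stim)

pc = net.cell_ids(CellType.PC, hc=0, mc=0)
mc = net.cell_ids(CellType.MC, hc=0, mc=0)
print("PC", round(binned_rate(res.spikes, pc).window_mean(200, 1200), 2),
      "MC", round(binned_rate(res.spikes, mc).window_mean(200, 1200), 2))
```

prints

```
PC 21.53 MC 12.67
```

i.e. the driven minicolumn's PC respond at ~21 Hz while its MC, recruited
through facilitating local and long-range synapses, fire at ~13 Hz
(background PC activity without a stimulus is ~0.5 Hz).  The experiment
runners in `columnet.protocols` wrap this into the four pre-registered
protocols (size-dependent suppression, contextual contrast, center-surround
delta across wiring variants, VIP disinhibition size series), each returning
rate traces, summary statistics and the fully resolved configuration.

A thin CLI mirrors the library:

```sh
columnet build --grid 3x3 --out nets/demo        # cells.csv, connections.csv
columnet calibrate                               # calibrated G per pathway
columnet run surround-suppression --grid 3x3 --trials 3 --out report.json
```

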