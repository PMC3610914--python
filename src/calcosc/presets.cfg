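# Simulation preset table.  Plain key = value; concentrations in uM,
# times in seconds, fluorescence in arbitrary units.
#
# The [base] section describes the day-5 spontaneous-activity condition.
# freq_target sets the candidate Poisson rate through the dead-time
# relation lambda = mu / (1 - mu * refractory); peak_target sets the
# transient peak by bisection so the detected event amplitude (F/F0) of a
# noiseless single transient equals the target.

[base]
dt = 1.0
f_base = 100
noise_sd = 2.0          # 2% of f_base
drift_amp = 0.03
drift_period = 150
freq_target = 0.042     # Hz, detected oscillation frequency to reproduce
refractory = 15
tau_rise = 2.0
tau_decay = 6.0
peak_target = 2.01      # F/F0, detected event amplitude to reproduce

# Drug concentration-response multipliers (Hill form).  Ketamine acts on
# the transient peak from low-tens uM and on the event rate only at
# hundreds of uM; MK-801 suppresses both; NMDA potentiates the peak at
# ~100 uM with a steep high-concentration action on the rate.

[modulation ketamine_rate]
drug = ketamine
applies_to = event_rate
direction = inhibit
half_conc = 300
hill_slope = 2
max_effect = 1.0

[modulation ketamine_peak]
drug = ketamine
applies_to = peak_df
direction = inhibit
half_conc = 100
hill_slope = 1.5
max_effect = 0.7

[modulation mk801]
drug = mk801
applies_to = both
direction = inhibit
half_conc = 10
hill_slope = 1
max_effect = 0.8

[modulation nmda_peak]
drug = nmda
applies_to = peak_df
direction = potentiate
half_conc = 150
hill_slope = 2
max_effect = 2.5

[modulation nmda_rate]
drug = nmda
applies_to = event_rate
direction = potentiate
half_conc = 600
hill_slope = 3
max_effect = 16

[preset baseline_d5]
doses =

[preset nmda_100]
doses = nmda:100

[preset mk801_40]
doses = mk801:40

[preset ketamine_1]
doses = ketamine:1

[preset ketamine_3]
doses = ketamine:3

[preset ketamine_10]
doses = ketamine:10

[preset ketamine_30]
doses = ketamine:30

[preset ketamine_100]
doses = ketamine:100

[preset ketamine_300]
doses = ketamine:300

[preset ketamine_1000]
doses = ketamine:1000

[preset ketamine_3000]
doses = ketamine:3000
rate_override = 0       # complete abolition of spontaneous events

[preset reversal_nmda_100]
doses = ketamine:1000, nmda:100

[preset reversal_nmda_300]
doses = ketamine:1000, nmda:300

[preset reversal_nmda_1000]
doses = ketamine:1000, nmda:1000
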