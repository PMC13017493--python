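"""Temperature-response constants for C3 photosynthesis kinetics.

Values transcribed from Bernacchi et al. (2001, Plant, Cell & Environment
24:253-259) for Kc, Ko, Gamma*, Vcmax and Rd, and from Bernacchi et al.
(2003, Plant, Cell & Environment 26:1419-1430) for the electron-transport
rate J.  Each entry gives the value at 25 degC (in the unit noted) and the
activation energy Ha in kJ mol-1 of the Arrhenius response

    f(T) = value25 * exp(Ha / R * (1/298.15 - 1/T_K))

with R = 8.314e-3 kJ mol-1 K-1.  Do not edit values without citing a
source; this file is the versioned constants record.

version: bernacchi-2001/2003, transcription 1
"""

R_KJ = 8.314e-3  # gas constant, kJ mol-1 K-1
T25_K = 298.15

# (value at 25 degC, activation energy Ha [kJ mol-1])
KC_25, KC_HA = 404.9, 79.43            # umol mol-1
KO_25, KO_HA = 278.4, 36.38            # mmol mol-1
GAMMA_STAR_25, GAMMA_STAR_HA = 42.75, 37.83  # umol mol-1
VCMAX_HA = 65.33                       # kJ mol-1 (scaling only; no absolute value)
RD_HA = 46.39                          # kJ mol-1
J_HA = 43.5                            # kJ mol-1 (Bernacchi et al. 2003)

OXYGEN_MMOL = 210.0  # ambient O2 mole fraction, mmol mol-1 (21 kPa / 100 kPa)
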