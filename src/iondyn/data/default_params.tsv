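# Minimal nonbonded parameter table (GROMACS units: charge e, sigma nm, epsilon kJ/mol).
# Columns: resname  atomname  q  sigma  epsilon
# resname "*"    -> matches any residue by atom name
# resname "ELEM" -> matches by element symbol (last-resort fallback)
# Divalent-cation CM-model parameters; protein heavy atoms carry generic
# CHARMM-like LJ values with zero net charge (backbone/sidechain partial
# charges beyond ions are not needed for the shipped analyses).
ZN    ZN    2.000   0.226466454151   0.01381916624
CA    CA    2.000   0.293818397243   0.44320568080
MG    MG    2.000   0.21000          0.00500
NA    NA    1.000   0.24299          0.01960
CL    CL   -1.000   0.43000          0.30000
HOH   O    -0.834   0.315057         0.63627
HOH   OW   -0.834   0.315057         0.63627
HOH   H1    0.417   0.040001         0.19246
HOH   H2    0.417   0.040001         0.19246
*     N    -0.470   0.329632         0.83680
*     CA    0.070   0.356359         0.46024
*     C     0.510   0.356359         0.46024
*     O    -0.510   0.302905         0.50208
ELEM  C     0.000   0.356359         0.46024
ELEM  N     0.000   0.329632         0.83680
ELEM  O     0.000   0.302905         0.50208
ELEM  S     0.000   0.356359         1.88280
ELEM  H     0.000   0.040001         0.19246
ELEM  P     0.000   0.383000         2.44700
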