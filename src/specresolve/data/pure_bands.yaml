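# Default pure-component band tables for the four analytes of the quaternary
# cold-remedy mixture (paracetamol, ascorbic acid, caffeine, chlorpheniramine
# maleate in methanol). Each spectrum is a sum of Gaussian bands:
#     a(lambda) = sum_b height * exp(-0.5 * ((lambda - center_nm) / width_nm)^2)
# with height in AU * mL / ug at 1 cm path, i.e. absorptivity per unit
# concentration. Band positions emulate the qualitative picture of the real
# system — all four maxima crowd the 220–300 nm window and overlap severely —
# but the absolute absorptivities are synthetic design choices, not measured
# values.
#
# level_grid entries are the five calibration concentrations (ug/mL) used by
# the five-level, four-factor design.
analytes:
  - name: PARA
    level_grid: [4.00, 8.00, 12.00, 16.00, 20.00]
    bands:
      - {center_nm: 249.0, width_nm: 18.0, height: 0.048}
      - {center_nm: 262.0, width_nm: 14.0, height: 0.031}
  - name: ASC
    level_grid: [3.00, 6.00, 9.00, 12.00, 15.00]
    bands:
      - {center_nm: 251.0, width_nm: 12.0, height: 0.061}
      - {center_nm: 239.0, width_nm: 10.0, height: 0.018}
  - name: CAF
    level_grid: [2.50, 5.00, 7.50, 10.00, 12.50]
    bands:
      - {center_nm: 269.0, width_nm: 16.0, height: 0.086}
      - {center_nm: 243.0, width_nm: 14.0, height: 0.041}
  - name: CPM
    level_grid: [1.00, 3.00, 5.00, 7.00, 9.00]
    bands:
      - {center_nm: 263.0, width_nm: 17.0, height: 0.096}
      - {center_nm: 232.0, width_nm: 9.0, height: 0.072}
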