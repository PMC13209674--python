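# Ten LUAD driver scenarios encoded as gene-level counteraction targets.
# Direction: -1 = suppress an activated oncogenic signal,
#            +1 = restore a reduced protective function.
scenarios:
  - name: "Scenario 1"
    axis: "RTK activation"
    targets: {EGFR: -1, ERBB2: -1, MET: -1, ALK: -1, ROS1: -1}
  - name: "Scenario 2"
    axis: "EGFR exon 20 insertion"
    targets: {EGFR: -1, ERBB2: -1, ERBB3: -1}
  - name: "Scenario 3"
    axis: "KRAS pathway activation"
    targets: {KRAS: -1, PTPN11: -1, SOS1: -1, MAP2K1: -1, MAP2K2: -1, MAPK1: -1, MAPK3: -1}
  - name: "Scenario 4"
    axis: "STK11/KEAP1 co-alteration"
    targets: {STK11: 1, PRKAA1: 1, PRKAA2: 1, KEAP1: 1, NFE2L2: -1, GLS: -1}
  - name: "Scenario 5"
    axis: "BRAF-MAPK activation"
    targets: {BRAF: -1, MAP2K1: -1, MAP2K2: -1, MAPK1: -1, MAPK3: -1}
  - name: "Scenario 6"
    axis: "PI3K/AKT/mTOR activation"
    targets: {PIK3CA: -1, AKT1: -1, AKT2: -1, AKT3: -1, MTOR: -1, RPS6KB1: -1, PTEN: 1}
  - name: "Scenario 7"
    axis: "ERBB3-NRG1 activation"
    targets: {ERBB3: -1, ERBB2: -1, NRG1: -1, PIK3CA: -1}
  - name: "Scenario 8"
    axis: "DDR dysfunction with ATR dependency"
    targets: {ATR: -1, CHEK1: -1, WEE1: -1, PARP1: -1, ATM: 1, BRCA1: 1, BRCA2: 1}
  - name: "Scenario 9"
    axis: "RET/NTRK fusions"
    targets: {RET: -1, NTRK1: -1, NTRK2: -1, NTRK3: -1, MAP2K1: -1, MAP2K2: -1}
  - name: "Scenario 10"
    axis: "SMARCA4-deficient LUAD"
    targets: {SMARCA4: 1, SMARCA2: 1, EZH2: -1, CDK4: -1, CDK6: -1}
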