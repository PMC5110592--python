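description: 'Standard scoring key for the 50-item adult AQ: an item scores 1 when
  the response falls on the listed side of the 4-point scale (1=definitely agree ..
  4=definitely disagree). Editable; the key is instrument convention, not derived
  from any single dataset.'
cutoffs:
  clinical: 26
  nonclinical: 32
directions:
  item_1: disagree
  item_2: agree
  item_3: disagree
  item_4: agree
  item_5: agree
  item_6: agree
  item_7: agree
  item_8: disagree
  item_9: agree
  item_10: disagree
  item_11: disagree
  item_12: agree
  item_13: agree
  item_14: disagree
  item_15: disagree
  item_16: agree
  item_17: disagree
  item_18: agree
  item_19: agree
  item_20: agree
  item_21: agree
  item_22: agree
  item_23: agree
  item_24: disagree
  item_25: disagree
  item_26: agree
  item_27: disagree
  item_28: disagree
  item_29: disagree
  item_30: disagree
  item_31: disagree
  item_32: disagree
  item_33: agree
  item_34: disagree
  item_35: agree
  item_36: disagree
  item_37: disagree
  item_38: disagree
  item_39: agree
  item_40: disagree
  item_41: agree
  item_42: agree
  item_43: agree
  item_44: disagree
  item_45: agree
  item_46: agree
  item_47: disagree
  item_48: disagree
  item_49: disagree
  item_50: disagree
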