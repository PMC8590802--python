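id,sex,study_area,n_fixes,area_km2
B01,F,eastern,517,7.70
B02,F,eastern,82,8.00
B03,F,eastern,138,8.30
B04,F,eastern,173,20.45
B05,F,southern,139,23.35
B06,F,eastern,511,23.65
B07,F,eastern,552,23.95
B08,M,eastern,380,27.85
B09,M,eastern,54,28.14
B10,F,eastern,87,28.45
B11,F,southern,230,28.75
B12,M,eastern,290,48.65
B13,M,eastern,403,48.95
B14,M,eastern,318,49.25
B15,F,southern,189,49.55
B16,M,southern,126,49.84
B17,M,eastern,445,50.15
B18,F,southern,471,77.82
B19,M,southern,50,159.63
B20,M,southern,99,165.66
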