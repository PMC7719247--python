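factor_kind,level,climate_zone,value,uncertainty_pct
LU,long-term-cultivated,boreal-dry,0.8,12
LU,set-aside,boreal-dry,0.93,12
LU,perennial,boreal-dry,1.0,12
MG,CT,boreal-dry,1.0,10
MG,RT,boreal-dry,1.02,10
MG,NT,boreal-dry,1.1,10
MG,none,boreal-dry,1.0,10
I,low,boreal-dry,0.95,15
I,medium,boreal-dry,1.0,15
I,high,boreal-dry,1.04,15
I,high-with-amendment,boreal-dry,1.37,15
LU,long-term-cultivated,boreal-moist,0.69,12
LU,set-aside,boreal-moist,0.82,12
LU,perennial,boreal-moist,1.0,12
MG,CT,boreal-moist,1.0,10
MG,RT,boreal-moist,1.08,10
MG,NT,boreal-moist,1.15,10
MG,none,boreal-moist,1.0,10
I,low,boreal-moist,0.92,15
I,medium,boreal-moist,1.0,15
I,high,boreal-moist,1.11,15
I,high-with-amendment,boreal-moist,1.44,15
LU,long-term-cultivated,cold-temperate-dry,0.8,12
LU,set-aside,cold-temperate-dry,0.93,12
LU,perennial,cold-temperate-dry,1.0,12
MG,CT,cold-temperate-dry,1.0,10
MG,RT,cold-temperate-dry,1.02,10
MG,NT,cold-temperate-dry,1.1,10
MG,none,cold-temperate-dry,1.0,10
I,low,cold-temperate-dry,0.95,15
I,medium,cold-temperate-dry,1.0,15
I,high,cold-temperate-dry,1.04,15
I,high-with-amendment,cold-temperate-dry,1.37,15
LU,long-term-cultivated,cold-temperate-moist,0.69,12
LU,set-aside,cold-temperate-moist,0.82,12
LU,perennial,cold-temperate-moist,1.0,12
MG,CT,cold-temperate-moist,1.0,10
MG,RT,cold-temperate-moist,1.08,10
MG,NT,cold-temperate-moist,1.15,10
MG,none,cold-temperate-moist,1.0,10
I,low,cold-temperate-moist,0.92,15
I,medium,cold-temperate-moist,1.0,15
I,high,cold-temperate-moist,1.11,15
I,high-with-amendment,cold-temperate-moist,1.44,15
LU,long-term-cultivated,warm-temperate-dry,0.8,12
LU,set-aside,warm-temperate-dry,0.93,12
LU,perennial,warm-temperate-dry,1.0,12
MG,CT,warm-temperate-dry,1.0,10
MG,RT,warm-temperate-dry,1.02,10
MG,NT,warm-temperate-dry,1.1,10
MG,none,warm-temperate-dry,1.0,10
I,low,warm-temperate-dry,0.95,15
I,medium,warm-temperate-dry,1.0,15
I,high,warm-temperate-dry,1.04,15
I,high-with-amendment,warm-temperate-dry,1.37,15
LU,long-term-cultivated,warm-temperate-moist,0.69,12
LU,set-aside,warm-temperate-moist,0.82,12
LU,perennial,warm-temperate-moist,1.0,12
MG,CT,warm-temperate-moist,1.0,10
MG,RT,warm-temperate-moist,1.08,10
MG,NT,warm-temperate-moist,1.15,10
MG,none,warm-temperate-moist,1.0,10
I,low,warm-temperate-moist,0.92,15
I,medium,warm-temperate-moist,1.0,15
I,high,warm-temperate-moist,1.11,15
I,high-with-amendment,warm-temperate-moist,1.44,15
LU,long-term-cultivated,tropical-dry,0.58,12
LU,set-aside,tropical-dry,0.93,12
LU,perennial,tropical-dry,1.0,12
MG,CT,tropical-dry,1.0,10
MG,RT,tropical-dry,1.09,10
MG,NT,tropical-dry,1.17,10
MG,none,tropical-dry,1.0,10
I,low,tropical-dry,0.95,15
I,medium,tropical-dry,1.0,15
I,high,tropical-dry,1.04,15
I,high-with-amendment,tropical-dry,1.37,15
LU,long-term-cultivated,tropical-moist,0.48,12
LU,set-aside,tropical-moist,0.82,12
LU,perennial,tropical-moist,1.0,12
MG,CT,tropical-moist,1.0,10
MG,RT,tropical-moist,1.15,10
MG,NT,tropical-moist,1.22,10
MG,none,tropical-moist,1.0,10
I,low,tropical-moist,0.92,15
I,medium,tropical-moist,1.0,15
I,high,tropical-moist,1.11,15
I,high-with-amendment,tropical-moist,1.44,15
LU,long-term-cultivated,tropical-wet,0.48,12
LU,set-aside,tropical-wet,0.82,12
LU,perennial,tropical-wet,1.0,12
MG,CT,tropical-wet,1.0,10
MG,RT,tropical-wet,1.15,10
MG,NT,tropical-wet,1.22,10
MG,none,tropical-wet,1.0,10
I,low,tropical-wet,0.92,15
I,medium,tropical-wet,1.0,15
I,high,tropical-wet,1.11,15
I,high-with-amendment,tropical-wet,1.44,15
LU,long-term-cultivated,tropical-montane,0.64,12
LU,set-aside,tropical-montane,0.88,12
LU,perennial,tropical-montane,1.0,12
MG,CT,tropical-montane,1.0,10
MG,RT,tropical-montane,1.09,10
MG,NT,tropical-montane,1.16,10
MG,none,tropical-montane,1.0,10
I,low,tropical-montane,0.94,15
I,medium,tropical-montane,1.0,15
I,high,tropical-montane,1.08,15
I,high-with-amendment,tropical-montane,1.41,15
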