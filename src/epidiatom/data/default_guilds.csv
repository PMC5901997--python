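genus,max_size_um,guild
Labellicula,,motile
Nitzschia,,motile
Halamphora,,low_profile
Navicula,,motile
Entomoneis,,motile
Tursicola,,low_profile
Olifantiella,,motile
Amphora,,low_profile
Pseudo-nitzschia,,planktonic
Achnanthidium,,low_profile
Cocconeis,,low_profile
Gomphonema,,high_profile
Cymbella,,high_profile
Fragilaria,,high_profile
Melosira,,high_profile
Thalassiosira,,planktonic
Chaetoceros,,planktonic
Surirella,,motile
Gyrosigma,,motile
Diploneis,,motile
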