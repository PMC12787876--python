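participant,speed_kmh,fft_spm,peaks_spm,video_spm
1,6,134.92,100.50,123.94
2,6,126.17,112.50,121.18
3,6,126.17,100.71,123.97
4,6,166.17,148.64,166.82
5,6,114.93,85.91,115.82
6,6,138.67,31.36,141.88
7,6,134.92,73.75,130.26
8,6,127.42,95.77,133.49
9,6,152.42,140.00,156.09
10,6,126.17,87.27,119.76
11,6,126.17,95.45,122.32
1,8,149.92,108.75,152.30
2,8,158.67,184.50,156.06
3,8,158.67,165.00,161.52
4,8,168.66,169.09,170.57
5,8,147.42,135.00,149.41
6,8,151.17,83.18,151.28
7,8,177.41,171.82,167.70
8,8,163.67,160.91,183.92
9,8,163.67,110.00,164.27
10,8,151.17,91.36,156.45
11,8,148.67,139.50,141.63
1,10,154.92,143.75,159.07
2,10,161.17,175.50,175.56
3,10,186.16,198.00,177.31
4,10,172.41,173.18,174.03
5,10,151.17,151.36,154.89
6,10,157.42,102.27,160.72
7,10,188.66,160.38,170.95
8,10,168.66,171.82,194.01
9,10,171.16,162.27,175.90
10,10,162.42,136.36,163.82
11,10,151.17,143.18,146.66
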